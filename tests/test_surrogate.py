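import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from boicl import (
    Candidate,
    Completion,
    LabeledExample,
    Memory,
    PredictionDistribution,
    PromptTemplate,
    build_prompt,
    consistency_std,
    inverse_design,
    parse_completion,
    predict_distribution,
    propose_inverse_target,
    weighted_mean,
    weighted_std,
)
from boicl.errors import PredictionFailureError, TemplateError
from boicl.synthetic import MockBackend

from conftest import vec_candidate


class TableBackend:
    """Returns a fixed list of completions regardless of the prompt."""

    name = "table"

    def __init__(self, completions):
        self._completions = completions

    def sample(self, prompt, temperature, n_samples):
        assert n_samples == len(self._completions)
        return self._completions


def dist(values, weights, n_raw=None):
    values = np.asarray(values, float)
    weights = np.asarray(weights, float)
    weights = weights / weights.sum()
    weights[-1] = 1.0 - weights[:-1].sum()
    return PredictionDistribution(
        values, weights, n_raw=n_raw or len(values), n_parsed=len(values)
    )


# -- prompts -----------------------------------------------------------------


def test_build_prompt_single_example_matches_template():
    tpl = PromptTemplate(prefix="Answer with a number.\n", property_name="solubility")
    context = [LabeledExample(Candidate("a", "A", np.array([1.0, 0.0])), 2.5)]
    query = Candidate("q", "B", np.array([0.0, 1.0]))
    prompt = build_prompt(tpl, context, query)
    assert prompt.startswith("Answer with a number.\n")
    assert "Given A. What is solubility? 2.5\n" in prompt
    assert prompt.endswith("Given B. What is solubility?")


def test_build_prompt_empty_context_is_prefix_plus_suffix():
    tpl = PromptTemplate(prefix="P|", property_name="yield")
    query = vec_candidate("q", [1, 0])
    assert build_prompt(tpl, [], query) == f"P|Given {query.text}. What is yield?"


def test_build_prompt_preserves_context_order():
    tpl = PromptTemplate()
    context = [
        LabeledExample(vec_candidate(cid, [1, i]), float(i))
        for i, cid in enumerate(["z", "m", "a"])
    ]
    prompt = build_prompt(tpl, context, vec_candidate("q", [0, 1]))
    positions = [prompt.index(ex.candidate.text) for ex in context]
    assert positions == sorted(positions)


def test_template_missing_slot_rejected():
    with pytest.raises(TemplateError):
        PromptTemplate(example_format="Given {representation}: {completion}\n")


# -- parsing -----------------------------------------------------------------


@pytest.mark.parametrize(
    "text, expected",
    [
        ("12.3", 12.3),
        ("The yield is 18.2%", 18.2),
        ("-4.5 units", -4.5),
        ("about 1e-3 mol", 1e-3),
        ("not applicable", None),
    ],
)
def test_parse_completion_first_number_rule(text, expected):
    assert parse_completion(text) == expected


# -- prediction distributions ------------------------------------------------


def test_identical_completions_give_degenerate_distribution():
    comps = [Completion("7.0", (0.0,))] * 5
    d = predict_distribution(TableBackend(comps), "p", n_samples=5)
    assert d.support.tolist() == [7.0]
    assert d.weights.tolist() == [1.0]
    assert not d.degenerate  # five completions parsed, support merely merged


def test_equal_logprob_completions_split_weight_evenly():
    comps = [Completion("1.0", (-0.3,)), Completion("3.0", (-0.3,))]
    d = predict_distribution(TableBackend(comps), "p", n_samples=2)
    assert d.weights == pytest.approx([0.5, 0.5])


def test_weights_follow_hand_evaluated_normalization():
    comps = [
        Completion("2", (math.log(0.5),)),
        Completion("2", (math.log(0.5),)),
        Completion("4", (math.log(1.0),)),
    ]
    d = predict_distribution(TableBackend(comps), "p", n_samples=3)
    # hand evaluation: raw weights exp(ln .5)=.5 twice on value 2 (merged -> 1.0)
    # and exp(ln 1)=1.0 on value 4; normalization gives 0.5 / 0.5
    assert d.support.tolist() == [2.0, 4.0]
    assert d.weights == pytest.approx([0.5, 0.5])
    assert d.n_parsed == 3 and d.n_raw == 3


def test_all_unparseable_raises_prediction_failure():
    comps = [Completion("n/a", (-0.1,))] * 2
    with pytest.raises(PredictionFailureError):
        predict_distribution(TableBackend(comps), "prompt about X", n_samples=2)


# -- moments -----------------------------------------------------------------


def test_weighted_mean_cases():
    assert weighted_mean(dist([0, 4], [0.25, 0.75])) == pytest.approx(3.0)
    assert weighted_mean(dist([7], [1.0])) == pytest.approx(7.0)
    rng = np.random.default_rng(2)
    v, w = rng.normal(size=6), rng.uniform(0.1, 1, 6)
    d = dist(v, w)
    assert weighted_mean(d) == pytest.approx(float(np.sum(v * w) / w.sum()))
    assert min(v) <= weighted_mean(d) <= max(v)


def test_weighted_std_equal_weights_reduces_to_sample_std():
    d = dist([2.0, 4.0], [0.5, 0.5])
    assert weighted_std(d) == pytest.approx(math.sqrt(2.0), abs=1e-12)


def test_weighted_std_identical_values_zero_and_single_value_degenerate():
    assert weighted_std(dist([3.0, 3.0], [0.4, 0.6], n_raw=2)) == pytest.approx(0.0)
    single = dist([5.0], [1.0])
    assert single.degenerate
    assert weighted_std(single) == 0.0


def test_weighted_std_matches_direct_formula_evaluation():
    values, weights = [1.0, 2.0, 6.0], [0.2, 0.3, 0.5]
    d = dist(values, weights)
    # direct evaluation of the weighted-spread formula with N = 3
    xbar = sum(w * x for w, x in zip(weights, values))
    var = sum(w * (x - xbar) ** 2 for w, x in zip(weights, values)) / ((2 / 3) * 1.0)
    assert weighted_std(d) == pytest.approx(math.sqrt(var), abs=1e-12)


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=12))
def test_equal_weight_weighted_std_equals_consistency_std(values):
    d = dist(values := list(dict.fromkeys(values)) or [0.0, 1.0], np.ones(len(values)))
    assert weighted_std(d) == pytest.approx(consistency_std(values), rel=1e-9, abs=1e-9)


def test_consistency_std_closed_forms():
    assert consistency_std([3, 3, 3]) == pytest.approx(0.0)
    assert consistency_std([2, 4]) == pytest.approx(math.sqrt(2))
    assert consistency_std([1, 2, 3, 4]) == pytest.approx(1.29099, abs=1e-5)
    assert consistency_std([5.0]) == 0.0


# -- inverse design ----------------------------------------------------------


def test_inverse_target_zero_incumbent_stays_zero():
    rng = np.random.default_rng(0)
    assert propose_inverse_target(0.0, rng) == 0.0


def test_inverse_target_monte_carlo_moments():
    rng = np.random.default_rng(123)
    draws = np.array([propose_inverse_target(10.0, rng) for _ in range(10_000)])
    assert draws.mean() == pytest.approx(12.0, abs=0.05)
    assert draws.std(ddof=1) == pytest.approx(0.5, abs=0.02)
    neg = np.array([propose_inverse_target(-10.0, rng) for _ in range(5_000)])
    assert neg.mean() == pytest.approx(-8.0, abs=0.05)


def _procedure_memory(embedder, labels):
    mem = Memory()
    for i, y in enumerate(labels):
        text = f"procedure variant {i} with reagent R{i}"
        mem.add(LabeledExample(Candidate(f"p{i}", text, embedder.embed(text)), y))
    return mem


def test_inverse_design_echoes_label_nearest_text(embedder):
    mem = _procedure_memory(embedder, [1.0, 8.0, 4.0])
    backend = MockBackend({ex.candidate.text: ex.label for ex in mem})
    # incumbent is 8.0 (p1); the mock echoes the first (label-nearest) context
    x_prime = inverse_design(backend, mem, y_prime=9.6, k=2)
    assert x_prime == "procedure variant 1 with reagent R1"


def test_inverse_design_single_example_context(embedder):
    mem = _procedure_memory(embedder, [3.0])
    backend = MockBackend({ex.candidate.text: ex.label for ex in mem})
    assert inverse_design(backend, mem, y_prime=3.6, k=5) == mem.examples[0].candidate.text


# -- determinism -------------------------------------------------------------


def test_prediction_is_bit_reproducible_with_seeded_mock():
    truth = {"alpha recipe": 4.0, "beta recipe": 6.0}
    prompt = "Given alpha recipe. What is the objective?"
    d1 = predict_distribution(MockBackend(truth, noise_sd=0.7, seed=9), prompt, 5)
    d2 = predict_distribution(MockBackend(truth, noise_sd=0.7, seed=9), prompt, 5)
    assert d1.support.tolist() == d2.support.tolist()
    assert d1.weights.tolist() == d2.weights.tolist()
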