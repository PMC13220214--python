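"""The in-context-learning surrogate: prompts, completions, distributions.

A frozen text-completion model serves as the probabilistic surrogate.
For each query, labeled examples retrieved from memory are formatted
into a few-shot prompt; the backend samples ``n`` completions at
temperature ``T``; each parsed numeric completion ``x_i`` receives a
weight ``w_i`` derived from its token log-probabilities; and the set
``{(x_i, w_i)}`` forms a discrete predictive distribution with weighted
mean

    xbar = sum_i w_i x_i / sum_i w_i

and weighted standard deviation

    sigma = sqrt( sum_i w_i (x_i - xbar)^2 / ( ((N-1)/N) * sum_i w_i ) )

which reduces to the unbiased sample standard deviation when all weights
are equal. Inverse design runs the same machinery label-to-text: the
backend is asked for a hypothetical procedure ``x'`` matching a target
label ``y'`` slightly above the incumbent; ``x'`` never enters the pool —
only its embedding is used as the MMR retrieval reference.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .errors import PredictionFailureError, TemplateError
from .memory import Candidate, LabeledExample, Memory

_NUMBER_RE = re.compile(r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?")


@dataclass(frozen=True)
class PromptTemplate:
    """Prompt structure ``{prefix}{few-shot examples}{suffix}``.

    ``example_format`` must contain the slots ``{representation}``,
    ``{property_name}`` and ``{completion}``; ``suffix_format`` contains
    ``{representation}`` and ``{property_name}``. The prefix carries the
    task description and admissible-design constraints (typically sent as
    a system message) to hedge against hallucinated out-of-space outputs.
    """

    prefix: str = ""
    example_format: str = "Given {representation}. What is {property_name}? {completion}\n"
    suffix_format: str = "Given {representation}. What is {property_name}?"
    property_name: str = "the objective"

    def __post_init__(self) -> None:
        for slot in ("{representation}", "{property_name}", "{completion}"):
            if slot not in self.example_format:
                raise TemplateError(f"example_format is missing slot {slot}")
        for slot in ("{representation}", "{property_name}"):
            if slot not in self.suffix_format:
                raise TemplateError(f"suffix_format is missing slot {slot}")


#: label-to-text mirror of the regression template, used for inverse design
INVERSE_TEMPLATE = PromptTemplate(
    prefix="",
    example_format="Given {property_name} of {completion}. What is the procedure? {representation}\n",
    suffix_format="Given {property_name} of {representation}. What is the procedure?",
    property_name="the objective",
)


@dataclass(frozen=True)
class Completion:
    """One sampled completion: text plus per-token log-probabilities."""

    text: str
    token_logprobs: tuple[float, ...]

    def __post_init__(self) -> None:
        lps = tuple(float(x) for x in self.token_logprobs)
        if any(lp > 1e-9 for lp in lps):
            raise ValueError("token log-probabilities must be <= 0")
        object.__setattr__(self, "token_logprobs", lps)

    @property
    def mean_logprob(self) -> float:
        if not self.token_logprobs:
            return 0.0
        return float(sum(self.token_logprobs) / len(self.token_logprobs))


@runtime_checkable
class CompletionBackend(Protocol):
    """Contract for a frozen text-completion model.

    ``sample`` must return exactly ``n_samples`` completions for the
    prompt at sampling temperature ``temperature``. Hosted-API adapters
    implement this same contract; the package ships deterministic mocks.
    """

    name: str

    def sample(self, prompt: str, temperature: float, n_samples: int) -> list[Completion]: ...


class TranscriptRecorder:
    """Backend wrapper logging every prompt/completion exchange.

    Wraps any :class:`CompletionBackend` transparently; the audit trail
    can be flushed to JSONL (one exchange per line).
    """

    def __init__(self, backend: CompletionBackend):
        self.backend = backend
        self.name = f"recorded:{backend.name}"
        self.records: list[dict] = []

    def sample(self, prompt: str, temperature: float, n_samples: int) -> list[Completion]:
        completions = self.backend.sample(prompt, temperature, n_samples)
        self.records.append(
            {
                "prompt": prompt,
                "temperature": temperature,
                "n_samples": n_samples,
                "completions": [
                    {"text": c.text, "token_logprobs": list(c.token_logprobs)}
                    for c in completions
                ],
            }
        )
        return completions

    def write_jsonl(self, path) -> None:
        import json
        from pathlib import Path

        with open(Path(path), "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec) + "\n")


def build_prompt(
    template: PromptTemplate,
    context: Sequence[LabeledExample],
    query: Candidate,
) -> str:
    """Render prefix, then one example block per context item (in retrieval
    order), then the query suffix. Deterministic."""
    parts = [template.prefix]
    for ex in context:
        parts.append(
            template.example_format.format(
                representation=ex.candidate.text,
                property_name=template.property_name,
                completion=_format_label(ex.label),
            )
        )
    parts.append(
        template.suffix_format.format(
            representation=query.text, property_name=template.property_name
        )
    )
    return "".join(parts)


def _format_label(label: float) -> str:
    return format(label, "g")


def parse_completion(text: str) -> float | None:
    """First signed decimal number in the text; ``None`` if there is none."""
    m = _NUMBER_RE.search(text)
    if m is None:
        return None
    try:
        return float(m.group(0))
    except ValueError:  # pragma: no cover - regex guarantees parseability
        return None


@dataclass(frozen=True)
class PredictionDistribution:
    """Discrete predictive distribution over parsed completion values.

    ``support`` holds the distinct parsed values, ``weights`` their
    normalized probabilities. ``degenerate`` flags the single-value case
    where the spread-based uncertainty is structurally zero.
    """

    support: np.ndarray
    weights: np.ndarray
    n_raw: int
    n_parsed: int

    def __post_init__(self) -> None:
        s = np.asarray(self.support, dtype=np.float64)
        w = np.asarray(self.weights, dtype=np.float64)
        if s.shape != w.shape or s.ndim != 1 or s.size == 0:
            raise ValueError("support and weights must be equal-length 1-D arrays")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")
        if self.n_parsed > self.n_raw or self.n_parsed < 1:
            raise ValueError("need 1 <= n_parsed <= n_raw")
        s.flags.writeable = False
        w.flags.writeable = False
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "weights", w)

    @property
    def degenerate(self) -> bool:
        return self.n_parsed < 2

    def mean(self) -> float:
        return weighted_mean(self)

    def std(self) -> float:
        return weighted_std(self)


def predict_distribution(
    backend: CompletionBackend,
    prompt: str,
    n_samples: int = 5,
    temperature: float = 0.7,
) -> PredictionDistribution:
    """Sample ``n_samples`` completions and form the predictive distribution.

    Each completion's raw weight is ``exp(mean per-token log-probability)``
    (the geometric-mean token probability, which is length-invariant);
    completions parsing to the same value are merged by summing weights;
    unparseable completions are dropped. If nothing parses, a
    :class:`~boicl.errors.PredictionFailureError` is raised.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    completions = backend.sample(prompt, temperature, n_samples)
    if len(completions) != n_samples:
        raise ValueError(
            f"backend returned {len(completions)} completions, expected {n_samples}"
        )
    merged: dict[float, float] = {}
    n_parsed = 0
    for comp in completions:
        value = parse_completion(comp.text)
        if value is None:
            continue
        n_parsed += 1
        merged[value] = merged.get(value, 0.0) + math.exp(comp.mean_logprob)
    if not merged:
        raise PredictionFailureError(
            f"none of {n_samples} completions parsed to a number "
            f"(prompt tail: {prompt[-80:]!r})"
        )
    support = np.array(sorted(merged), dtype=np.float64)
    weights = np.array([merged[v] for v in support], dtype=np.float64)
    weights = weights / weights.sum()
    # renormalize exactly so the sum-to-one invariant holds bit-tight
    weights[-1] = 1.0 - weights[:-1].sum()
    return PredictionDistribution(support, weights, n_raw=n_samples, n_parsed=n_parsed)


def weighted_mean(dist: PredictionDistribution) -> float:
    """``sum w_i x_i / sum w_i``; always inside the support hull."""
    return float(dist.support @ dist.weights / dist.weights.sum())


def weighted_std(dist: PredictionDistribution) -> float:
    """Weighted spread with the unbiased ``(N-1)/N`` small-sample factor.

    ``N`` is the number of parsed completions. With a single parsed value
    the spread is structurally zero (the distribution is flagged
    degenerate rather than raising).
    """
    n = dist.n_parsed
    if n < 2:
        return 0.0
    xbar = weighted_mean(dist)
    wsum = dist.weights.sum()
    var = float(dist.weights @ (dist.support - xbar) ** 2) / (((n - 1) / n) * wsum)
    return math.sqrt(max(var, 0.0))


def consistency_std(values: Sequence[float]) -> float:
    """Unbiased sample standard deviation of repeated predictions.

    A consistency-based uncertainty proxy that ignores token
    probabilities entirely; returns 0 for fewer than two values
    (degenerate case)."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 2:
        return 0.0
    return float(np.std(arr, ddof=1))


def propose_inverse_target(y_plus: float, rng: np.random.Generator) -> float:
    """Target label for inverse design: ``y' = y+ + |y+| * N(0.2, 0.05)``.

    The relative bump of ~20% asks the model for a design slightly better
    than the incumbent; for ``y+ = 0`` the target is 0.
    """
    return float(y_plus + abs(y_plus) * rng.normal(0.2, 0.05))


def inverse_design(
    backend: CompletionBackend,
    memory: Memory,
    y_prime: float,
    k: int,
    template: PromptTemplate = INVERSE_TEMPLATE,
    temperature: float = 0.7,
) -> str:
    """Generate a hypothetical design text ``x'`` for target label ``y'``.

    Context is the ``k`` memory examples with labels nearest the incumbent
    ``y+``, rendered label-to-text; the backend is queried once (a single
    inverse-design round). The returned text is used only as an MMR
    retrieval reference, never added to the pool.
    """
    incumbent = memory.best_observed()
    context = memory.retrieve_by_label(incumbent.label, k)
    parts = [template.prefix]
    for ex in context:
        parts.append(
            template.example_format.format(
                representation=ex.candidate.text,
                property_name=template.property_name,
                completion=_format_label(ex.label),
            )
        )
    parts.append(
        template.suffix_format.format(
            representation=_format_label(y_prime), property_name=template.property_name
        )
    )
    prompt = "".join(parts)
    completions = backend.sample(prompt, temperature, 1)
    return completions[0].text
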