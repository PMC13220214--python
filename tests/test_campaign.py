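import itertools
import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from boicl import (
    AcquisitionConfig,
    Campaign,
    CampaignConfig,
    HashingEmbedder,
    MMRConfig,
    MockBackend,
    SyntheticPoolConfig,
    corrupt_labels,
    expected_random_max,
    generate_pool,
    percentile_rank,
    run_campaign,
)
from boicl.errors import (
    DuplicateObservationError,
    ObservationError,
    UnknownCandidateError,
)
from boicl.synthetic import MockBackend as _Mock
from boicl.surrogate import Completion


@pytest.fixture(scope="module")
def small_setup():
    config = SyntheticPoolConfig(n_candidates=40, seed=5)
    pool, labels = generate_pool(config)
    embedder = HashingEmbedder()
    truth = {pool.get(cid).text: labels[cid] for cid in pool.ids}
    return pool, labels, truth, embedder


def _campaign_config(**kwargs):
    defaults = dict(
        max_iterations=5,
        seed=1,
        k_context=3,
        mmr=MMRConfig(subpool_size=100),  # clipped to whole pool
        acquisition=AcquisitionConfig(kind="greedy"),
    )
    defaults.update(kwargs)
    return CampaignConfig(**defaults)


def test_ask_with_oracle_surrogate_and_greedy_returns_true_best(small_setup):
    pool, labels, truth, embedder = small_setup
    backend = MockBackend(truth, noise_sd=0.0)  # perfect predictions, sigma = 0
    campaign = Campaign(pool, _campaign_config(), backend=backend, embedder=embedder)
    campaign.seed_initial(lambda cid: labels[cid])
    cand, mu, sigma = campaign.ask()
    unlabeled_best = max((labels[c.id], c.id) for c in campaign.unlabeled)
    assert labels[cand.id] == unlabeled_best[0]
    assert mu == pytest.approx(labels[cand.id])
    assert sigma == pytest.approx(0.0)


class ConstantMeanBackend:
    """Predicts the same mean everywhere with candidate-specific spread."""

    name = "constant-mean"

    def __init__(self, truth, sigmas):
        self._mock = _Mock(truth)
        self._sigmas = sigmas

    def sample(self, prompt, temperature, n_samples):
        from boicl.synthetic import _INVERSE_SUFFIX_RE, _QUERY_RE

        if _INVERSE_SUFFIX_RE.search(prompt):
            return self._mock.sample(prompt, temperature, n_samples)
        text = _QUERY_RE.findall(prompt)[-1]
        sigma = self._sigmas[text]
        offsets = _Mock._quantile_offsets(n_samples)
        return [Completion(format(5.0 + sigma * o, ".10g"), (-0.05,)) for o in offsets]


def test_ucb_with_flat_means_picks_highest_sigma(small_setup):
    pool, labels, truth, embedder = small_setup
    rng = np.random.default_rng(0)
    sigmas = {text: float(rng.uniform(0.1, 2.0)) for text in truth}
    backend = ConstantMeanBackend(truth, sigmas)
    cfg = _campaign_config(acquisition=AcquisitionConfig(kind="ucb", lambda_ucb=1.0))
    campaign = Campaign(pool, cfg, backend=backend, embedder=embedder)
    campaign.seed_initial(lambda cid: labels[cid])
    cand, _, sigma = campaign.ask()
    expected = max(
        ((sigmas[c.text], c.id) for c in campaign.unlabeled), key=lambda t: (t[0], t[1])
    )
    assert cand.id == expected[1]
    assert sigma == pytest.approx(expected[0], rel=1e-6)


def test_fixed_seed_gives_identical_trajectories(small_setup):
    pool, labels, truth, embedder = small_setup

    def run_once():
        backend = MockBackend(truth, noise_sd=0.5, seed=3)
        return run_campaign(
            pool, lambda cid: labels[cid], _campaign_config(seed=2),
            backend=backend, embedder=embedder,
        )

    assert run_once() == run_once()


def test_tell_bookkeeping_and_errors(small_setup):
    pool, labels, truth, embedder = small_setup
    backend = MockBackend(truth)
    campaign = Campaign(pool, _campaign_config(), backend=backend, embedder=embedder)
    n0 = len(campaign.unlabeled)
    first = pool.ids[0]
    campaign.tell(first, 4.0)
    assert len(campaign.unlabeled) == n0 - 1
    assert campaign.best_so_far == 4.0
    campaign.tell(pool.ids[1], 2.0)
    assert campaign.best_so_far == 4.0  # worse label leaves the incumbent
    with pytest.raises(DuplicateObservationError):
        campaign.tell(first, 1.0)
    with pytest.raises(UnknownCandidateError):
        campaign.tell("nope", 1.0)
    with pytest.raises(ObservationError):
        campaign.tell(pool.ids[2], math.nan)
    # memory and unlabeled pool partition the original pool
    ids = {c.id for c in campaign.unlabeled} | {
        ex.candidate.id for ex in campaign.memory
    }
    assert ids == set(pool.ids)


def test_best_so_far_nondecreasing_and_schedule_runs(small_setup):
    pool, labels, truth, embedder = small_setup
    backend = MockBackend(truth, noise_sd=0.3, seed=1)
    cfg = _campaign_config(
        max_iterations=6,
        acquisition=AcquisitionConfig(kind="ucb", schedule="ei:1-3,greedy:4-6"),
    )
    traj = run_campaign(pool, lambda cid: labels[cid], cfg, backend=backend, embedder=embedder)
    bests = [rec.best_so_far for rec in traj]
    assert bests == sorted(bests)
    assert len(traj) == cfg.n_seed + 6


def test_stop_threshold_terminates_on_pool_max(small_setup):
    pool, labels, truth, embedder = small_setup
    best = max(labels.values())
    backend = MockBackend(truth, noise_sd=0.0)
    cfg = _campaign_config(max_iterations=40, stop_threshold=best)
    traj = run_campaign(pool, lambda cid: labels[cid], cfg, backend=backend, embedder=embedder)
    assert traj[-1].best_so_far == pytest.approx(best)
    # with a perfect greedy surrogate over the full pool the maximum is
    # found on the first iteration after seeding (unless seeded directly)
    assert len(traj) <= cfg.n_seed + 1


def test_zero_iterations_yields_seed_only_trajectory(small_setup):
    pool, labels, truth, embedder = small_setup
    backend = MockBackend(truth)
    cfg = _campaign_config(max_iterations=0, n_seed=3)
    traj = run_campaign(pool, lambda cid: labels[cid], cfg, backend=backend, embedder=embedder)
    assert len(traj) == 3
    assert all(rec.iteration == 0 for rec in traj)


def test_random_arm_ignores_surrogate(small_setup):
    pool, labels, truth, embedder = small_setup
    backend = MockBackend(truth)
    cfg = _campaign_config(acquisition=AcquisitionConfig(kind="random"), max_iterations=4)
    traj = run_campaign(pool, lambda cid: labels[cid], cfg, backend=backend, embedder=embedder)
    assert len(traj) == cfg.n_seed + 4
    assert all(math.isnan(rec.predicted_mu) for rec in traj if rec.iteration > 0)


# -- analysis helpers --------------------------------------------------------


def test_percentile_rank_cases():
    assert percentile_rank([1, 2, 3], 3) == 100.0
    assert percentile_rank([1, 2, 3, 4], 1) == 25.0
    grid = list(range(1, 101))
    assert percentile_rank(grid, 50) == 50.0


def test_expected_random_max_closed_form_and_enumeration():
    assert expected_random_max(100, 1) == pytest.approx(50.5)
    assert expected_random_max(100, 100) == pytest.approx(100.0)
    assert expected_random_max(100, 3) == pytest.approx(75.75)
    # exhaustive enumeration over all C(10, 3) draws
    n, t = 10, 3
    mean_max = np.mean([max(c) for c in itertools.combinations(range(1, n + 1), t)])
    assert expected_random_max(n, t) == pytest.approx(mean_max)
    with pytest.raises(ValueError):
        expected_random_max(10, 11)


def test_corrupt_labels_preserves_marginal_and_kills_association():
    rng = np.random.default_rng(0)
    labels = rng.normal(size=1000)
    corrupted = corrupt_labels(labels, np.random.default_rng(1))
    assert sorted(corrupted) == pytest.approx(sorted(labels))
    rho = spearmanr(labels, corrupted).statistic
    assert abs(rho) < 0.1
    again = corrupt_labels(labels, np.random.default_rng(1))
    assert np.array_equal(corrupted, again)
    resampled = corrupt_labels(labels, np.random.default_rng(2), mode="resample")
    assert set(resampled) <= set(labels)
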