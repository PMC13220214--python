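"""The ask-tell campaign engine and trajectory analysis helpers.

One iteration of the language-model-surrogate loop:

1. propose an inverse-design target ``y'`` slightly above the incumbent,
2. generate a hypothetical design text ``x'`` conditioned on ``y'``,
3. MMR-retrieve a subpool of unlabeled candidates around ``embed(x')``,
4. predict a distribution for each subpool member from few-shot prompts,
5. score ``alpha(mu, scale * sigma)`` and return the top candidate.

``tell`` moves the labeled candidate from the unlabeled pool into
memory. The GP arm replaces steps 1-4 by scoring the full pool with a
Gaussian-process posterior on reduced embeddings; the random arm draws
uniformly. Module-level helpers cover percentile ranks, the analytic
expected best rank of random search, label corruption for null
controls, and Monte-Carlo envelopes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field

from . import acquisition as acq
from .errors import (
    CampaignError,
    DuplicateObservationError,
    ObservationError,
    PoolExhaustedError,
    PredictionFailureError,
    UnknownCandidateError,
)
from .gp import GPConfig, GPSurrogate, ReducerConfig
from .memory import Candidate, LabeledExample, Memory, Pool, seed_diverse
from .retrieval import EmbeddingProvider, MMRConfig, mmr_select
from .surrogate import (
    INVERSE_TEMPLATE,
    CompletionBackend,
    PromptTemplate,
    build_prompt,
    inverse_design,
    predict_distribution,
    propose_inverse_target,
    weighted_mean,
    weighted_std,
)

logger = logging.getLogger(__name__)


class CampaignConfig(BaseModel):
    """All knobs of one optimization campaign.

    Defaults follow the reference operating point: 5 few-shot context
    examples, sampling temperature 0.7, 5 completions per prompt, an
    uncertainty calibration factor of 5 (inside ``acquisition``), and
    2-point farthest-point diverse seeding.
    """

    k_context: int = Field(default=5, ge=1)
    temperature: float = Field(default=0.7, gt=0.0)
    n_completions: int = Field(default=5, ge=1)
    acquisition: acq.AcquisitionConfig = Field(default_factory=acq.AcquisitionConfig)
    mmr: MMRConfig = Field(default_factory=MMRConfig)
    seed: int = 0
    max_iterations: int = Field(default=30, ge=0)
    stop_threshold: Optional[float] = None
    initial_seeding: Literal["random", "diverse"] = "diverse"
    n_seed: int = Field(default=2, ge=1)
    surrogate: Literal["icl", "gp"] = "icl"
    reducer: ReducerConfig = Field(default_factory=ReducerConfig)
    gp: GPConfig = Field(default_factory=GPConfig)
    property_name: str = "the objective"
    system_message: str = ""


@dataclass(frozen=True)
class TrajectoryRecord:
    """One labeled experiment in campaign order (iteration 0 = seeding)."""

    iteration: int
    candidate_id: str
    predicted_mu: float
    predicted_sigma: float
    observed_label: float
    best_so_far: float


class Campaign:
    """Stateful ask-tell optimizer over a fixed candidate pool."""

    def __init__(
        self,
        pool: Pool,
        config: CampaignConfig,
        backend: CompletionBackend | None = None,
        embedder: EmbeddingProvider | None = None,
    ):
        if config.surrogate == "icl" and (backend is None or embedder is None):
            raise ValueError("the ICL surrogate needs a completion backend and an embedder")
        self.pool = pool
        self.config = config
        self.backend = backend
        self.embedder = embedder
        self.memory = Memory()
        self.trajectory: list[TrajectoryRecord] = []
        self.rng = np.random.default_rng(config.seed)
        self._unlabeled: dict[str, Candidate] = {c.id: c for c in pool}
        self._iteration = 0
        self._in_seeding = True  # tells before the first ask are seed observations
        self.template = PromptTemplate(
            prefix=config.system_message,
            property_name=config.property_name,
        )
        self.inverse_template = PromptTemplate(
            prefix=INVERSE_TEMPLATE.prefix,
            example_format=INVERSE_TEMPLATE.example_format,
            suffix_format=INVERSE_TEMPLATE.suffix_format,
            property_name=config.property_name,
        )
        self._gp: GPSurrogate | None = None
        if config.surrogate == "gp":
            self._gp = GPSurrogate.from_pool(pool, config.reducer, config.gp)

    # -- state ---------------------------------------------------------------

    @property
    def unlabeled(self) -> list[Candidate]:
        return list(self._unlabeled.values())

    @property
    def best_so_far(self) -> float:
        return self.memory.best_observed().label

    # -- seeding -------------------------------------------------------------

    def seed_initial(self, oracle: Callable[[str], float]) -> None:
        """Label the initial examples (random or farthest-point diverse)."""
        if self.config.initial_seeding == "random":
            ids = list(self._unlabeled)
            picks = [
                ids[i]
                for i in self.rng.choice(len(ids), size=self.config.n_seed, replace=False)
            ]
        else:
            ref = self.pool.ids[int(self.rng.integers(len(self.pool)))]
            picks = [c.id for c in seed_diverse(self.pool, ref, self.config.n_seed)]
        for cid in picks:
            self.tell(cid, oracle(cid))

    # -- ask -----------------------------------------------------------------

    def ask(self) -> tuple[Candidate, float, float]:
        """Select the next experiment; returns (candidate, mu, sigma).

        ``mu``/``sigma`` are NaN for the random arm, which predicts
        nothing.
        """
        if not self._unlabeled:
            raise PoolExhaustedError("all candidates have been labeled")
        self._in_seeding = False
        iteration = self._iteration + 1
        kind = self.config.acquisition.kind_for_iteration(iteration)
        if kind == "random":
            cand = acq.random_select(self.unlabeled, self.rng)
            return cand, math.nan, math.nan
        if len(self.memory) == 0:
            raise CampaignError("memory is empty; run seeding before ask")
        y_plus = self.best_observed_label()
        if self.config.surrogate == "gp":
            candidates = self.unlabeled
            mu, sigma = self._gp.predict(self.memory, candidates)
            predictions = list(zip(candidates, mu, sigma))
        else:
            predictions = self._predict_subpool()
        scored = [
            (c, acq.score(kind, float(m), float(s), self.config.acquisition, y_plus))
            for c, m, s in predictions
        ]
        ranked = acq.rank_candidates(scored)
        winner = ranked[0][0]
        mu_w, sigma_w = next(
            (float(m), float(s)) for c, m, s in predictions if c.id == winner.id
        )
        return winner, mu_w, sigma_w

    def best_observed_label(self) -> float:
        return self.memory.best_observed().label

    def _predict_subpool(self) -> list[tuple[Candidate, float, float]]:
        cfg = self.config
        subpool: dict[str, Candidate] = {}
        for _ in range(cfg.mmr.rounds):
            y_prime = propose_inverse_target(self.best_observed_label(), self.rng)
            x_prime = inverse_design(
                self.backend, self.memory, y_prime, cfg.k_context,
                template=self.inverse_template, temperature=cfg.temperature,
            )
            reference = self.embedder.embed(x_prime)
            for c in mmr_select(self.unlabeled, reference, cfg.mmr):
                subpool.setdefault(c.id, c)
        out: list[tuple[Candidate, float, float]] = []
        for c in subpool.values():
            context = self.memory.retrieve_by_text(c.embedding, cfg.k_context)
            prompt = build_prompt(self.template, context, c)
            try:
                dist = predict_distribution(
                    self.backend, prompt, cfg.n_completions, cfg.temperature
                )
            except PredictionFailureError:
                logger.warning("skipping candidate %s: no parseable completion", c.id)
                continue
            out.append((c, weighted_mean(dist), weighted_std(dist)))
        if not out:
            raise CampaignError(
                f"iteration {self._iteration + 1}: every subpool prediction failed"
            )
        return out

    # -- tell ----------------------------------------------------------------

    def tell(
        self,
        candidate_id: str,
        label: float,
        predicted_mu: float = math.nan,
        predicted_sigma: float = math.nan,
    ) -> None:
        """Report the measured label for a previously unlabeled candidate."""
        if not np.isfinite(label):
            raise ObservationError(f"label for {candidate_id!r} is not finite: {label!r}")
        if candidate_id in self.memory:
            raise DuplicateObservationError(f"{candidate_id!r} was already labeled")
        if candidate_id not in self._unlabeled:
            raise UnknownCandidateError(f"{candidate_id!r} is not in the unlabeled pool")
        cand = self._unlabeled.pop(candidate_id)
        self.memory.add(LabeledExample(cand, label))
        if self._in_seeding:
            iteration = 0
        else:
            self._iteration += 1
            iteration = self._iteration
        self.trajectory.append(
            TrajectoryRecord(
                iteration=iteration,
                candidate_id=candidate_id,
                predicted_mu=float(predicted_mu),
                predicted_sigma=float(predicted_sigma),
                observed_label=float(label),
                best_so_far=self.best_so_far,
            )
        )


def run_campaign(
    pool: Pool,
    oracle: Callable[[str], float],
    config: CampaignConfig,
    backend: CompletionBackend | None = None,
    embedder: EmbeddingProvider | None = None,
) -> list[TrajectoryRecord]:
    """Seed, then alternate ask/tell until the iteration budget or the
    stop threshold is reached. Returns the full trajectory (seed
    observations have iteration 0)."""
    campaign = Campaign(pool, config, backend=backend, embedder=embedder)
    campaign.seed_initial(oracle)
    for _ in range(config.max_iterations):
        if (
            config.stop_threshold is not None
            and campaign.best_so_far >= config.stop_threshold
        ):
            break
        if not campaign.unlabeled:
            break
        cand, mu, sigma = campaign.ask()
        try:
            label = oracle(cand.id)
        except Exception as err:
            raise CampaignError(
                f"oracle failed for {cand.id!r}; partial trajectory of "
                f"{len(campaign.trajectory)} records retained"
            ) from err
        campaign.tell(cand.id, label, predicted_mu=mu, predicted_sigma=sigma)
    return campaign.trajectory


# ---------------------------------------------------------------------------
# trajectory analysis


def percentile_rank(pool_labels: Sequence[float], value: float) -> float:
    """``100 * #{labels <= value} / N`` — the percentile of a label in the pool."""
    labels = np.asarray(pool_labels, dtype=np.float64)
    if labels.size == 0:
        raise ValueError("pool_labels must be non-empty")
    return float(100.0 * np.count_nonzero(labels <= value) / labels.size)


def expected_random_max(pool_size: int, draws: int) -> float:
    """Expected maximum rank of ``t`` uniform draws without replacement
    from ranks ``1..N``: ``t (N + 1) / (t + 1)``."""
    if draws < 1 or draws > pool_size:
        raise ValueError(f"need 1 <= draws <= pool_size, got t={draws}, N={pool_size}")
    return draws * (pool_size + 1) / (draws + 1)


def corrupt_labels(
    pool_labels: Sequence[float],
    rng: np.random.Generator,
    mode: Literal["permute", "resample"] = "permute",
) -> np.ndarray:
    """Destroy the feature-label association while preserving the marginal.

    ``permute`` reassigns the exact label multiset at random;
    ``resample`` draws with replacement from the empirical distribution.
    """
    labels = np.asarray(pool_labels, dtype=np.float64)
    if mode == "permute":
        return rng.permutation(labels)
    if mode == "resample":
        return rng.choice(labels, size=labels.size, replace=True)
    raise ValueError(f"unknown corruption mode {mode!r}")


def best_rank_trajectory(
    trajectory: Sequence[TrajectoryRecord], pool_labels: Sequence[float]
) -> np.ndarray:
    """Best rank (1..N, ties averaged) reached after each labeled experiment."""
    from scipy.stats import rankdata

    labels = np.asarray(pool_labels, dtype=np.float64)
    ranks = rankdata(labels)
    by_label = {}
    for lab, r in zip(labels, ranks):
        by_label[lab] = r
    traj_ranks = np.array([by_label[rec.observed_label] for rec in trajectory])
    return np.maximum.accumulate(traj_ranks)


def random_search_envelope(
    pool_size: int,
    t_max: int,
    n_replicates: int,
    rng: np.random.Generator,
    n_sim: int = 2000,
    coverage: float = 0.95,
) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneous Monte-Carlo envelope for the mean best-rank curve of
    random search.

    Simulates ``n_sim`` means over ``n_replicates`` independent
    without-replacement random-search trajectories on ranks ``1..N`` and
    returns per-step (lo, hi) bounds such that a fraction ``coverage``
    of simulated mean curves lies entirely inside the band (a global
    rank envelope, so the band is valid for the whole curve rather than
    pointwise)."""
    sims = np.empty((n_sim, t_max))
    for s in range(n_sim):
        acc = np.zeros(t_max)
        for _ in range(n_replicates):
            draws = rng.permutation(pool_size)[:t_max] + 1
            acc += np.maximum.accumulate(draws)
        sims[s] = acc / n_replicates
    sorted_sims = np.sort(sims, axis=0)
    best_band = (sorted_sims[0], sorted_sims[-1])
    for depth in range(1, n_sim // 2):
        lo, hi = sorted_sims[depth], sorted_sims[-1 - depth]
        inside = np.mean(np.all((sims >= lo - 1e-9) & (sims <= hi + 1e-9), axis=1))
        if inside < coverage:
            break
        best_band = (lo, hi)
    return best_band
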