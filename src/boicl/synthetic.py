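"""Synthetic design pools, embeddings and backends with known ground truth.

Emulates a catalyst-screening campaign described in natural language: a
factorial design space (metal, support, temperature, loading) rendered
through a fixed text template that is bijective with the parameters, a
smooth latent objective with one interaction and an optional abrupt
"sintering" cliff, a deterministic hashing embedding provider, and a
mock completion backend that answers regression prompts from a truth
table with controllable noise, bias and a planted miscalibration
factor. Everything runs offline and is exactly reproducible from a
seed, so every campaign stage — retrieval, inverse design, prediction,
calibration — is testable against known ground truth.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import BackendError
from .memory import Candidate, Pool
from .surrogate import Completion

# ---------------------------------------------------------------------------
# factorial design space


DEFAULT_METALS = ("Pt", "Pd", "Cu", "Ni", "Fe", "Co", "Mn", "Zn", "Ag", "Mo")
DEFAULT_SUPPORTS = ("SiO2", "Al2O3", "TiO2", "CeO2", "ZrO2", "MgO")
DEFAULT_TEMPERATURES = tuple(range(250, 550, 25))  # deg C, 12 levels
DEFAULT_LOADINGS = (0.5, 1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0)  # wt%

TEXT_TEMPLATE = "Catalyst with {loading} wt% {metal} on {support}, run at {temperature} C"

_TEXT_RE = re.compile(
    r"Catalyst with (?P<loading>[\d.]+) wt% (?P<metal>\w+) on (?P<support>\w+), "
    r"run at (?P<temperature>\d+) C"
)


@dataclass(frozen=True)
class SyntheticPoolConfig:
    """Design-space and objective settings for a generated pool.

    ``noise_sd`` is measurement noise added to the stored labels (the
    latent objective itself stays noise-free and queryable); the default
    is noiseless labels so that optimization analyses compare against an
    exactly known optimum. ``cliff`` switches the abrupt
    temperature-dependent deactivation term that breaks global
    smoothness, mimicking the sharp performance shifts real catalyst
    spaces exhibit.
    """

    n_candidates: int = 1000
    seed: int = 0
    noise_sd: float = 0.0
    cliff: bool = True
    metals: tuple[str, ...] = DEFAULT_METALS
    supports: tuple[str, ...] = DEFAULT_SUPPORTS
    temperatures: tuple[int, ...] = DEFAULT_TEMPERATURES
    loadings: tuple[float, ...] = DEFAULT_LOADINGS

    @property
    def grid_cardinality(self) -> int:
        return (
            len(self.metals) * len(self.supports) * len(self.temperatures) * len(self.loadings)
        )


class SyntheticObjective:
    """Latent scalar objective over the factorial space.

    A base yield plus smooth per-factor effects (Gaussian peaks in
    temperature and log-loading, fixed categorical effects for metal and
    support), one metal-by-support interaction, and an optional cliff:
    above a metal-specific sintering temperature the yield drops
    sharply. Effect tables are drawn once from the config seed, so the
    objective is a deterministic function of the parameters.
    """

    def __init__(self, config: SyntheticPoolConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        n_m, n_s = len(config.metals), len(config.supports)
        self._metal_eff = rng.normal(0.0, 2.5, n_m)
        self._support_eff = rng.normal(0.0, 1.5, n_s)
        self._interaction = rng.normal(0.0, 1.0, (n_m, n_s))
        self._t_opt = rng.uniform(300.0, 475.0)
        self._l_opt = float(rng.choice(config.loadings[2:-1]))
        self._t_sinter = rng.choice(
            np.asarray(config.temperatures)[len(config.temperatures) // 2 :], n_m
        )
        self._m_idx = {m: i for i, m in enumerate(config.metals)}
        self._s_idx = {s: i for i, s in enumerate(config.supports)}

    def __call__(self, metal: str, support: str, temperature: float, loading: float) -> float:
        i, j = self._m_idx[metal], self._s_idx[support]
        y = 10.0
        y += self._metal_eff[i] + self._support_eff[j] + self._interaction[i, j]
        y += 6.0 * np.exp(-(((temperature - self._t_opt) / 90.0) ** 2))
        y += 3.0 * np.exp(-(((np.log(loading) - np.log(self._l_opt)) / 0.8) ** 2))
        if self.config.cliff and temperature > self._t_sinter[i]:
            y -= 4.0
        return float(y)

    def grid_max(self) -> float:
        """Exhaustive maximum over the full factorial grid."""
        best = -np.inf
        c = self.config
        for m in c.metals:
            for s in c.supports:
                for t in c.temperatures:
                    for l in c.loadings:
                        best = max(best, self(m, s, t, l))
        return best


def render_text(metal: str, support: str, temperature: float, loading: float) -> str:
    return TEXT_TEMPLATE.format(
        loading=format(loading, "g"), metal=metal, support=support,
        temperature=format(temperature, "g"),
    )


def parse_text(text: str) -> dict:
    """Invert the text template back to its parameters (bijective render)."""
    m = _TEXT_RE.search(text)
    if m is None:
        raise ValueError(f"text does not match the design template: {text!r}")
    return {
        "metal": m.group("metal"),
        "support": m.group("support"),
        "temperature": float(m.group("temperature")),
        "loading": float(m.group("loading")),
    }


def generate_pool(
    config: SyntheticPoolConfig,
    embedder: "HashingEmbedder | None" = None,
) -> tuple[Pool, dict[str, float]]:
    """Sample a pool from the factorial grid and label it.

    Candidates are drawn without replacement from the full grid;
    ``labels[id] = objective(params) + Normal(0, noise_sd)``. Fully
    deterministic under the config seed.
    """
    c = config
    if c.n_candidates > c.grid_cardinality:
        raise ValueError(
            f"n_candidates={c.n_candidates} exceeds grid cardinality {c.grid_cardinality}"
        )
    embedder = embedder or HashingEmbedder()
    objective = SyntheticObjective(c)
    rng = np.random.default_rng(c.seed + 1)  # sampling stream, separate from effects
    chosen = rng.choice(c.grid_cardinality, size=c.n_candidates, replace=False)

    n_s, n_t, n_l = len(c.supports), len(c.temperatures), len(c.loadings)
    candidates: list[Candidate] = []
    labels: dict[str, float] = {}
    width = len(str(c.n_candidates - 1))
    for rank, flat in enumerate(chosen):
        flat = int(flat)
        m_i, rem = divmod(flat, n_s * n_t * n_l)
        s_i, rem = divmod(rem, n_t * n_l)
        t_i, l_i = divmod(rem, n_l)
        metal, support = c.metals[m_i], c.supports[s_i]
        temperature, loading = c.temperatures[t_i], c.loadings[l_i]
        text = render_text(metal, support, temperature, loading)
        cid = f"cand-{rank:0{width}d}"
        candidates.append(Candidate(cid, text, embedder.embed(text)))
        y = objective(metal, support, temperature, loading)
        if c.noise_sd > 0:
            y += float(rng.normal(0.0, c.noise_sd))
        labels[cid] = y
    return Pool(candidates, provenance="synthetic"), labels


# ---------------------------------------------------------------------------
# deterministic embedding provider


class HashingEmbedder:
    """Seeded hash-based text featurization behind the embedding contract.

    Each token maps to a fixed pseudo-random direction (seeded by a
    stable digest of the token), a text embeds as the normalized sum of
    its token vectors, so texts sharing more tokens are closer in cosine
    similarity — a coarse but deterministic stand-in for a semantic
    embedding model.
    """

    def __init__(self, dimension: int = 256, seed: int = 0):
        self.name = f"hashing-{dimension}"
        self.dimension = dimension
        self.seed = seed
        self._token_cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._token_cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}|{token}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "big") >> 1)
            vec = rng.standard_normal(self.dimension)
            self._token_cache[token] = vec
        return vec

    def embed(self, text: str) -> np.ndarray:
        tokens = re.findall(r"[A-Za-z0-9.]+", text)
        if not tokens:
            raise ValueError("cannot embed empty text")
        acc = np.zeros(self.dimension)
        for tok in tokens:
            acc += self._token_vector(tok)
        n = np.linalg.norm(acc)
        if n == 0.0:  # pragma: no cover - sum of random vectors
            raise ValueError("degenerate embedding")
        return acc / n


def deterministic_embedding(text: str, dimension: int = 256, seed: int = 0) -> np.ndarray:
    """One-shot hashing embedding (unit vector); see :class:`HashingEmbedder`."""
    return HashingEmbedder(dimension=dimension, seed=seed).embed(text)


# ---------------------------------------------------------------------------
# mock completion backend

_QUERY_RE = re.compile(r"Given (.+?)\. What is ")
_INVERSE_SUFFIX_RE = re.compile(r"What is the procedure\?\s*$")
_INVERSE_ECHO_RE = re.compile(r"What is the procedure\? (.+?)\n")


class MockBackend:
    """Deterministic completion backend answering from a truth table.

    Regression prompts (the default few-shot template) are resolved by
    extracting the final query representation and looking it up in the
    truth table. Each call draws one query-level error
    ``e ~ Normal(bias, noise_sd)`` shared by all ``n_samples``
    completions, then spreads the completions around ``truth + e`` with
    deterministic standardized normal-quantile offsets whose sample
    standard deviation equals ``noise_sd / miscalibration``. The
    reported (spread-based) uncertainty therefore understates the actual
    error by exactly the planted miscalibration factor, while the
    prediction error itself has standard deviation ``noise_sd``.

    Inverse-design prompts (label-to-text template) are answered by
    echoing the first context procedure in the prompt — the memory
    example with the label nearest the incumbent.
    """

    def __init__(
        self,
        truth: dict[str, float],
        noise_sd: float = 0.0,
        bias: float = 0.0,
        miscalibration: float = 1.0,
        seed: int = 0,
    ):
        if miscalibration <= 0:
            raise ValueError("miscalibration factor must be > 0")
        if noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        self.name = "mock"
        self.truth = dict(truth)
        self.noise_sd = noise_sd
        self.bias = bias
        self.miscalibration = miscalibration
        self.rng = np.random.default_rng(seed)

    @staticmethod
    def _quantile_offsets(n: int) -> np.ndarray:
        if n == 1:
            return np.zeros(1)
        q = norm.ppf((np.arange(n) + 0.5) / n)
        q = q - q.mean()
        return q / q.std(ddof=1)

    def sample(self, prompt: str, temperature: float, n_samples: int) -> list[Completion]:
        if _INVERSE_SUFFIX_RE.search(prompt):
            return self._sample_inverse(prompt, n_samples)
        matches = _QUERY_RE.findall(prompt)
        if not matches:
            raise BackendError("mock backend could not locate a query in the prompt")
        text = matches[-1]
        if text not in self.truth:
            raise BackendError(f"mock backend has no truth for query text {text!r}")
        t = self.truth[text]
        e = float(self.rng.normal(self.bias, self.noise_sd)) if self.noise_sd > 0 else self.bias
        spread = self.noise_sd / self.miscalibration
        values = t + e + spread * self._quantile_offsets(n_samples)
        return [Completion(format(v, ".10g"), (-0.05,)) for v in values]

    def _sample_inverse(self, prompt: str, n_samples: int) -> list[Completion]:
        m = _INVERSE_ECHO_RE.search(prompt)
        if m is None:
            raise BackendError("inverse-design prompt carries no context procedure to echo")
        return [Completion(m.group(1), (-0.05,))] * n_samples


def mock_backend(
    truth: dict[str, float],
    noise_sd: float = 0.0,
    bias: float = 0.0,
    miscalibration: float = 1.0,
    seed: int = 0,
) -> MockBackend:
    """Factory matching the backend contract; see :class:`MockBackend`."""
    return MockBackend(truth, noise_sd=noise_sd, bias=bias,
                       miscalibration=miscalibration, seed=seed)
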