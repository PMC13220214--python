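"""Embedding-provider contract, cosine similarity, and MMR subpool selection.

Maximal marginal relevance (MMR) greedily builds a subpool that stays
relevant to a query embedding while penalizing redundancy with what has
already been picked:

    MMR pick = argmax_{d in pool \\ S} [ lam * Sim(d, q)
                                         - (1 - lam) * max_{s in S} Sim(d, s) ]

with the diversity term taken as 0 while S is empty. ``lam = 1`` reduces
to a plain similarity ranking; ``lam = 0`` is pure diversity.
"""

from __future__ import annotations

import logging
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from pydantic import BaseModel, Field

from .errors import DimensionMismatchError, ZeroVectorError
from .memory import Candidate, Pool

logger = logging.getLogger(__name__)

_TIE_TOL = 1e-12


@runtime_checkable
class EmbeddingProvider(Protocol):
    """Maps text to a fixed-dimension real vector, deterministically.

    Implementations must return the identical vector for identical text
    within one provider instance; ``dimension`` is constant. Real API
    providers (e.g. hosted embedding endpoints) are adapters behind this
    same contract; the package ships a deterministic hashing provider.
    """

    name: str
    dimension: int

    def embed(self, text: str) -> np.ndarray: ...


class MMRConfig(BaseModel):
    """Relevance/diversity trade-off ``lambda_mmr`` and subpool size."""

    lambda_mmr: float = Field(default=0.5, ge=0.0, le=1.0)
    subpool_size: int = Field(default=10, ge=1)
    # extra inverse-design/MMR passes per iteration are supported but a
    # single round is the default behavior
    rounds: int = Field(default=1, ge=1)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); raises on zero vectors or mismatched dimensions."""
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    if u.shape != v.shape:
        raise DimensionMismatchError(f"shapes {u.shape} and {v.shape} differ")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ZeroVectorError("cosine similarity is undefined for a zero vector")
    return float(u @ v / (nu * nv))


def mmr_select(
    pool: Pool | Sequence[Candidate],
    query_embedding: np.ndarray,
    config: MMRConfig,
) -> list[Candidate]:
    """Greedy MMR selection of a subpool ordered by pick sequence.

    Returns ``subpool_size`` distinct candidates; if the pool is smaller,
    the size is clipped with a warning. Ties at any step are broken by
    lexicographic candidate id.
    """
    candidates = list(pool)
    if not candidates:
        raise ValueError("cannot select from an empty pool")
    n_select = config.subpool_size
    if n_select > len(candidates):
        logger.warning(
            "subpool_size %d exceeds pool size %d; clipping", n_select, len(candidates)
        )
        n_select = len(candidates)

    q = np.asarray(query_embedding, dtype=np.float64)
    qn = np.linalg.norm(q)
    if qn == 0.0:
        raise ZeroVectorError("query embedding has zero norm")
    q = q / qn
    mat = np.stack([c.embedding for c in candidates])
    if mat.shape[1] != q.shape[0]:
        raise DimensionMismatchError(
            f"query dimension {q.shape[0]} != pool dimension {mat.shape[1]}"
        )

    lam = config.lambda_mmr
    sim_q = mat @ q
    ids = np.array([c.id for c in candidates])
    available = np.ones(len(candidates), dtype=bool)
    selected: list[int] = []
    max_sim_sel = np.full(len(candidates), -np.inf)  # max Sim to selected set

    for step in range(n_select):
        diversity = max_sim_sel if selected else 0.0
        scores = lam * sim_q - (1.0 - lam) * diversity
        scores = np.where(available, scores, -np.inf)
        top = scores.max()
        tied = np.flatnonzero(scores >= top - _TIE_TOL)
        best_i = int(tied[np.argmin(ids[tied])])  # lexicographic id tie-break
        selected.append(best_i)
        available[best_i] = False
        max_sim_sel = np.maximum(max_sim_sel, mat @ mat[best_i])
    return [candidates[i] for i in selected]
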