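"""Candidate pools and the labeled long-term memory of an ask-tell campaign.

The design space is a pool of candidates, each a natural-language
description of an experiment plus a unit-normalized embedding vector.
Labeled observations accumulate in a :class:`Memory`, which supports
exact cosine-similarity retrieval (for prompt context) and
label-proximity retrieval (for inverse design), and tracks the incumbent
``y+`` — the best objective value observed so far.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .errors import (
    DimensionMismatchError,
    DuplicateObservationError,
    EmptyMemoryError,
    UnknownCandidateError,
)

_NORM_ATOL = 1e-9


def _normalize(vec: np.ndarray) -> np.ndarray:
    v = np.asarray(vec, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("candidate embedding has zero norm")
    out = v / n
    out.flags.writeable = False
    return out


@dataclass(frozen=True)
class Candidate:
    """One design point: an id, its text representation, and its embedding.

    The embedding is unit-normalized at construction so that cosine
    similarity reduces to a dot product everywhere downstream.
    """

    id: str
    text: str
    embedding: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "embedding", _normalize(self.embedding))

    @property
    def dimension(self) -> int:
        return int(self.embedding.shape[0])


@dataclass(frozen=True)
class LabeledExample:
    """A candidate together with its observed objective value."""

    candidate: Candidate
    label: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.label):
            raise ValueError(f"label must be finite, got {self.label!r}")
        object.__setattr__(self, "label", float(self.label))


class Pool:
    """An ordered collection of unique candidates (the sample space)."""

    def __init__(self, candidates: Iterable[Candidate], provenance: str = "synthetic"):
        self._candidates: list[Candidate] = list(candidates)
        if not self._candidates:
            raise ValueError("a pool must contain at least one candidate")
        self._by_id: dict[str, Candidate] = {}
        dim = self._candidates[0].dimension
        for c in self._candidates:
            if c.id in self._by_id:
                raise ValueError(f"duplicate candidate id {c.id!r} in pool")
            if c.dimension != dim:
                raise DimensionMismatchError(
                    f"candidate {c.id!r} has dimension {c.dimension}, expected {dim}"
                )
            self._by_id[c.id] = c
        self.provenance = provenance

    def __len__(self) -> int:
        return len(self._candidates)

    def __iter__(self) -> Iterator[Candidate]:
        return iter(self._candidates)

    def __contains__(self, candidate_id: str) -> bool:
        return candidate_id in self._by_id

    def get(self, candidate_id: str) -> Candidate:
        try:
            return self._by_id[candidate_id]
        except KeyError:
            raise UnknownCandidateError(f"unknown candidate id {candidate_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self._candidates]

    @property
    def dimension(self) -> int:
        return self._candidates[0].dimension

    def embedding_matrix(self) -> np.ndarray:
        return np.stack([c.embedding for c in self._candidates])


class Memory:
    """Labeled examples with an exact embedding index for retrieval."""

    def __init__(self, examples: Iterable[LabeledExample] = ()):
        self._examples: list[LabeledExample] = []
        self._ids: set[str] = set()
        self._index: np.ndarray | None = None  # |M| x d, rebuilt lazily
        for ex in examples:
            self.add(ex)

    def __len__(self) -> int:
        return len(self._examples)

    def __iter__(self) -> Iterator[LabeledExample]:
        return iter(self._examples)

    @property
    def examples(self) -> Sequence[LabeledExample]:
        return tuple(self._examples)

    def __contains__(self, candidate_id: str) -> bool:
        return candidate_id in self._ids

    def add(self, example: LabeledExample) -> None:
        """Record a new observation; rejects repeated experiments."""
        cid = example.candidate.id
        if cid in self._ids:
            raise DuplicateObservationError(
                f"candidate {cid!r} already has an observed label"
            )
        if self._examples and example.candidate.dimension != self.dimension:
            raise DimensionMismatchError(
                f"embedding dimension {example.candidate.dimension} != index {self.dimension}"
            )
        self._examples.append(example)
        self._ids.add(cid)
        self._index = None

    @property
    def dimension(self) -> int:
        if not self._examples:
            raise EmptyMemoryError("memory is empty; dimension undefined")
        return self._examples[0].candidate.dimension

    def _matrix(self) -> np.ndarray:
        if self._index is None:
            self._index = np.stack([ex.candidate.embedding for ex in self._examples])
        return self._index

    def best_observed(self) -> LabeledExample:
        """The incumbent: maximal label, ties broken by earliest insertion."""
        if not self._examples:
            raise EmptyMemoryError("cannot take best_observed of empty memory")
        best = self._examples[0]
        for ex in self._examples[1:]:
            if ex.label > best.label:
                best = ex
        return best

    def retrieve_by_text(self, query_embedding: np.ndarray, k: int) -> list[LabeledExample]:
        """Top-``min(k, |M|)`` examples by cosine similarity, descending.

        Ties are broken lexicographically by candidate id so retrieval is
        bit-reproducible. If fewer than ``k`` examples are stored, all are
        returned.
        """
        if k < 1:
            raise ValueError("k must be positive")
        if not self._examples:
            return []
        q = np.asarray(query_embedding, dtype=np.float64)
        mat = self._matrix()
        if q.shape != (mat.shape[1],):
            raise DimensionMismatchError(
                f"query has shape {q.shape}, index dimension is {mat.shape[1]}"
            )
        qn = np.linalg.norm(q)
        if qn == 0.0:
            raise ValueError("query embedding has zero norm")
        sims = mat @ (q / qn)
        order = sorted(
            range(len(self._examples)),
            key=lambda i: (-sims[i], self._examples[i].candidate.id),
        )
        return [self._examples[i] for i in order[: min(k, len(order))]]

    def retrieve_by_label(self, target_label: float, k: int) -> list[LabeledExample]:
        """Top-``min(k, |M|)`` examples nearest ``target_label`` in absolute
        label difference, ascending; ties broken by candidate id."""
        if not self._examples:
            raise EmptyMemoryError("cannot retrieve from empty memory")
        if k < 1:
            raise ValueError("k must be positive")
        order = sorted(
            range(len(self._examples)),
            key=lambda i: (
                abs(self._examples[i].label - target_label),
                self._examples[i].candidate.id,
            ),
        )
        return [self._examples[i] for i in order[: min(k, len(order))]]

    # -- persistence (embeddings are re-derivable from text, so not stored) --

    def to_json(self, path: str | Path) -> None:
        payload = [
            {"id": ex.candidate.id, "text": ex.candidate.text, "label": ex.label}
            for ex in self._examples
        ]
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path, embedder) -> "Memory":
        payload = json.loads(Path(path).read_text())
        mem = cls()
        for row in payload:
            cand = Candidate(row["id"], row["text"], embedder.embed(row["text"]))
            mem.add(LabeledExample(cand, row["label"]))
        return mem


def add_observation(memory: Memory, example: LabeledExample) -> Memory:
    """Functional alias for :meth:`Memory.add`; returns the memory."""
    memory.add(example)
    return memory


def best_observed(memory: Memory) -> LabeledExample:
    return memory.best_observed()


def retrieve_context_by_text(
    memory: Memory, query_embedding: np.ndarray, k: int
) -> list[LabeledExample]:
    return memory.retrieve_by_text(query_embedding, k)


def retrieve_context_by_label(
    memory: Memory, target_label: float, k: int
) -> list[LabeledExample]:
    return memory.retrieve_by_label(target_label, k)


def seed_diverse(pool: Pool, reference_id: str, k: int) -> list[Candidate]:
    """Farthest-point seeding of the initial labeled set.

    Starting from the reference candidate, iteratively adds the candidate
    maximizing the minimum cosine distance (1 - cosine similarity) to all
    already-selected candidates, producing a maximally diverse seed set.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k > len(pool):
        raise ValueError(f"k={k} exceeds pool size {len(pool)}")
    reference = pool.get(reference_id)
    candidates = list(pool)
    mat = pool.embedding_matrix()
    idx_of = {c.id: i for i, c in enumerate(candidates)}

    selected = [reference]
    selected_idx = [idx_of[reference_id]]
    # min over selected of cosine distance to each pool member
    min_dist = 1.0 - mat @ mat[selected_idx[0]]
    while len(selected) < k:
        best_i = None
        for i, c in enumerate(candidates):
            if i in selected_idx:
                continue
            if (
                best_i is None
                or min_dist[i] > min_dist[best_i] + 1e-12
                or (abs(min_dist[i] - min_dist[best_i]) <= 1e-12 and c.id < candidates[best_i].id)
            ):
                best_i = i
        selected.append(candidates[best_i])
        selected_idx.append(best_i)
        min_dist = np.minimum(min_dist, 1.0 - mat @ mat[best_i])
    return selected
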