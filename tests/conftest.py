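import numpy as np
import pytest

from boicl import (
    Candidate,
    HashingEmbedder,
    LabeledExample,
    Memory,
    Pool,
    SyntheticPoolConfig,
    generate_pool,
)


def vec_candidate(cid: str, vec) -> Candidate:
    """Candidate with an explicit (to-be-normalized) embedding."""
    return Candidate(cid, f"text-{cid}", np.asarray(vec, dtype=float))


def random_pool(n: int, dim: int, rng: np.random.Generator) -> Pool:
    return Pool(
        [vec_candidate(f"c{i:03d}", rng.standard_normal(dim)) for i in range(n)]
    )


def memory_of(labeled: list[tuple[str, list, float]]) -> Memory:
    mem = Memory()
    for cid, vec, label in labeled:
        mem.add(LabeledExample(vec_candidate(cid, vec), label))
    return mem


@pytest.fixture
def embedder() -> HashingEmbedder:
    return HashingEmbedder(dimension=64, seed=0)


@pytest.fixture(scope="session")
def study_pool():
    """The 1000-candidate synthetic study pool with noiseless labels."""
    config = SyntheticPoolConfig(n_candidates=1000, seed=0)
    pool, labels = generate_pool(config)
    return pool, labels
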