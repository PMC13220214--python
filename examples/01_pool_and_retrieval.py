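"""Build a synthetic design pool and explore retrieval over it.

Generates 200 catalyst procedures described in natural language, embeds
them with the deterministic hashing provider, and shows farthest-point
seeding and MMR subpool selection around a query.
"""

import numpy as np

from boicl import (
    HashingEmbedder,
    MMRConfig,
    SyntheticPoolConfig,
    generate_pool,
    mmr_select,
    seed_diverse,
)

pool, labels = generate_pool(SyntheticPoolConfig(n_candidates=200, seed=0))
print(f"pool of {len(pool)} candidates, e.g.:")
first = next(iter(pool))
print(f"  {first.id}: {first.text!r}  (objective {labels[first.id]:.2f})")

# farthest-point seeding: maximally diverse initial experiments
seeds = seed_diverse(pool, reference_id=first.id, k=3)
print("\ndiverse seed set (reference first, then farthest points):")
for c in seeds:
    print(f"  {c.id}: {c.text}")

# MMR subpool around the best candidate's embedding: relevant but not redundant
embedder = HashingEmbedder()
best_id = max(labels, key=labels.get)
query = pool.get(best_id).embedding
subpool = mmr_select(pool, query, MMRConfig(lambda_mmr=0.5, subpool_size=5))
print(f"\nMMR subpool (lambda=0.5) around the pool optimum {best_id}:")
for c in subpool:
    sim = float(c.embedding @ query)
    print(f"  {c.id}  sim={sim:.3f}  objective={labels[c.id]:.2f}")
print(
    "\nThe first pick is the most similar candidate; later picks trade"
    "\nsimilarity against redundancy with what was already selected."
)
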