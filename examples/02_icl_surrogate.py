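"""Few-shot prompting and predictive distributions from a mock backend.

Builds a retrieval-augmented prompt for one query, samples five
completions through the deterministic mock completion backend, and forms
the weighted predictive distribution (mean and spread) from the parsed
values and their token probabilities.
"""

from boicl import (
    HashingEmbedder,
    LabeledExample,
    Memory,
    MockBackend,
    PromptTemplate,
    SyntheticPoolConfig,
    build_prompt,
    generate_pool,
    predict_distribution,
)

pool, labels = generate_pool(SyntheticPoolConfig(n_candidates=100, seed=1))
embedder = HashingEmbedder()
truth = {pool.get(cid).text: labels[cid] for cid in pool.ids}

# put 10 labeled examples into memory
memory = Memory()
for cid in pool.ids[:10]:
    memory.add(LabeledExample(pool.get(cid), labels[cid]))

query = pool.get(pool.ids[50])
context = memory.retrieve_by_text(query.embedding, k=5)
template = PromptTemplate(
    prefix="You predict the yield of catalyst procedures. Answer with a number.\n",
    property_name="the yield",
)
prompt = build_prompt(template, context, query)
print("prompt sent to the backend:\n---")
print(prompt)
print("---")

backend = MockBackend(truth, noise_sd=0.8, seed=3)
dist = predict_distribution(backend, prompt, n_samples=5, temperature=0.7)
print(f"\nparsed {dist.n_parsed}/{dist.n_raw} completions")
print("support :", [round(x, 3) for x in dist.support])
print("weights :", [round(w, 3) for w in dist.weights])
print(f"mu = {dist.mean():.3f}, sigma = {dist.std():.3f}  (truth {labels[query.id]:.3f})")
print(
    "\nmu is the token-probability-weighted mean of the sampled values;"
    "\nsigma is the weighted spread that the acquisition functions consume."
)
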