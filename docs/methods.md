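# Methods

This note documents the model, the synthetic study conditions, the
numerical choices, and the known limitations of the package. It states
no empirical result beyond what the test suite and
`scripts/acceptance.py` compute.

## The surrogate and its uncertainty

The optimizer treats a frozen text-completion model as a stochastic
regressor. For a query candidate, `n_completions` (default 5)
completions are sampled at temperature `T` (default 0.7) from a prompt
holding the `k_context` (default 5) most cosine-similar labeled
examples. Each completion's first signed decimal number is its parsed
value; completions with no number are dropped (never imputed), and a
candidate whose completions all fail to parse is skipped with a logged
prediction failure.

Each parsed value is weighted by `exp(mean per-token log-probability)`
— the geometric-mean token probability. The mean rather than the sum is
used so that a completion's weight does not depend on how many tokens
the model spent writing the number; duplicated values are merged by
summing weights, and weights are renormalized to 1. The spread

    sigma = sqrt( sum_i w_i (x_i - xbar)^2 / ( ((N-1)/N) * sum_i w_i ) )

uses `N` = number of parsed completions. The `(N-1)/N` factor is chosen
so that at equal weights sigma reduces exactly to the unbiased sample
standard deviation — which also makes it coincide with the
consistency-based uncertainty (`consistency_std`, the plain sample
standard deviation of repeated predictions) in that case. With a single
parsed value sigma is 0 and the distribution is flagged degenerate
rather than raising.

## Inverse design and subpool construction

Rather than scoring the whole pool (expensive with a real model per
query), each iteration asks the backend label-to-text for a
hypothetical procedure matching a target `y' = y+ + |y+|*N(0.2, 0.05)`
— roughly 20% above the incumbent; the Normal draw is not truncated, so
targets slightly below `y+` are possible and harmless. The context for
this inverse prompt is the `k` examples with labels nearest `y+`
(nearest by absolute difference; "similar labels" is not otherwise
defined). The generated text is used only as an MMR retrieval
reference. MMR runs with `lambda_mmr = 0.5` and `subpool_size = 10` by
default — both exposed in config, since neither value is canonical —
and a single inverse-design/MMR round per iteration (`mmr.rounds`
extends this; rounds union their subpools). All retrieval ties break on
lexicographic candidate id, and embeddings are unit-normalized at
ingest so cosine similarity is a dot product; together these make runs
bit-reproducible.

## Acquisition

UCB (`mu + lambda*sigma`, default `lambda = 1`), greedy (`mu`),
closed-form expected improvement (`xi = 0` default, with the
`sigma -> 0` limit `max(mu - y+ - xi, 0)`), and a uniform random
baseline. The global uncertainty calibration factor
(`uncertainty_scale`, default 5) multiplies sigma before any
acquisition consumes it; for UCB this is algebraically identical to
scaling lambda, so the two knobs are redundant by design — the scale is
a property of the surrogate's calibration, lambda of the
exploration policy. Maximization is assumed throughout; minimization
problems negate labels at ingest. Acquisition schedules such as
`"ei:1-7,greedy:8-10"` switch kinds across (1-based) iterations.

## Calibration

Coverage is defined by central Gaussian intervals: a level-`p` interval
is `mu ± z_{(1+p)/2}*sigma`, evaluated on 99 evenly spaced levels
0.01..0.99 (the number and placement of levels is a free choice; a
denser grid changes the area negligibly since the empirical curve has
at most `n` jumps). The miscalibration area is the trapezoidal area
between observed coverage and the diagonal, bounded by 0.5. The scaling
factor is fitted by exhaustive search on a fixed log-spaced grid
(0.25–20, 101 points — about a 4.4% step), ties to the smallest scale;
a grid search keeps the 1-D fit reproducible and free of optimizer
state.

A 25-point validation set identifies the scale only up to substantial
sampling noise: with independent Gaussian residuals the information
bound alone puts any scale estimate near a 14% relative standard
deviation, and the MA-minimizing estimator measures at roughly 16%, so
individual 25-point fits scatter around the true factor (the recovery
simulations in the acceptance suite quantify exactly this). The fit is
median-centered on the planted factor, and scaling essentially always
reduces the miscalibration area; growing the validation set far beyond
the small-sample regime moves the fitted scale by no more than a grid
step.

## The GP comparison arm

The GP arm replaces steps 1–4 of ask: pool embeddings are reduced once
per campaign with Isomap (default 32 output dimensions, 10 neighbors;
a disconnected neighborhood graph is an error advising more neighbors),
coordinates are standardized, and a `Constant*RBF (+White)` kernel GP
with marginal-likelihood hyperparameter fitting scores the full
unlabeled pool (no inverse-design subsampling — that step exists to
limit model-query cost, which the GP does not have). Ill-conditioned
kernel matrices escalate diagonal jitter from 1e-10 to 1e-2 before
failing. With `optimize=False` the posterior is exactly the closed-form
GP equations, which the tests verify against a hand-coded oracle.

With very few training points in 32 dimensions the fitted length scale
can collapse and the posterior go flat, at which point greedy selection
degenerates to the deterministic id-order tie-break — harmless for
optimization (it is an arbitrary-but-fixed scan) but a reason the
null-control replicates must be independent (below).

## Synthetic study conditions

The generator emulates a catalyst-screening pool: a factorial space of
10 metals x 6 supports x 12 temperatures (250–525 °C) x 8 loadings
(0.5–10 wt%), each candidate rendered through a fixed bijective text
template. The latent objective is a base yield plus fixed categorical
effects, smooth Gaussian peaks in temperature and log-loading, one
metal-by-support interaction, and a cliff: above a metal-specific
sintering temperature the yield drops by 4 units, mimicking the abrupt
performance shifts of real catalyst spaces. Effect tables are drawn
once from the pool seed. Default study pool: 1000 candidates sampled
without replacement from the grid, noiseless labels (the surrogate,
not the oracle, carries the noise in the studies).

The hashing embedder maps each token to a fixed pseudo-random
direction and normalizes the token-vector sum, so texts sharing more
parameter tokens are closer in cosine — a coarse, deterministic
stand-in for semantic embeddings. The mock completion backend answers
regression prompts from a truth table: per query it draws one error
`e ~ N(bias, noise_sd)` shared by the `n` completions and spreads the
completions deterministically (standardized normal quantiles) so the
reported sigma equals `noise_sd / miscalibration` exactly, while the
prediction error has standard deviation `noise_sd`. Campaign studies
use `noise_sd` = 5% of the pool label range.

What passing tests therefore show: the loop's mechanics (retrieval,
weighting, acquisition, bookkeeping, calibration) are correct, the
engine exploits a feature-label relationship when one exists and
degrades to random search when it is destroyed. What they do not show:
anything about real LLM behavior — the mock is an idealized regressor
whose errors are Gaussian and whose inverse designs are memory echoes;
real completion models hallucinate, drift with prompt phrasing, and
have non-Gaussian, input-dependent error structure.

## Benchmark and null-control design

- Campaign studies label 30 candidates: 2 farthest-point seeds (the
  seeding reference is drawn at random under the campaign seed) plus
  28 ask/tell iterations, on the 1000-candidate pool; five replicates
  per BO configuration with nonparametric comparison.
- Trajectories are summarized as best observed rank (ties averaged)
  after each labeled experiment. The random baseline admits the closed
  form `E[best rank of t draws] = t(N+1)/(t+1)`; Monte-Carlo envelopes
  for the mean-of-replicates curve use a global rank envelope
  (simultaneous, not pointwise, coverage).
- Null control: each replicate draws an independent permutation of the
  labels. Replicates must not share one permutation: if the surrogate
  carries no signal, its selection order can be deterministic (see the
  GP length-scale collapse above), and five trajectories measured
  against a single shared permutation are perfectly correlated rather
  than five independent null draws.
- Dominance of a BO arm over random is tested one-sided
  (Mann-Whitney) on the final best rank at the 30-experiment budget,
  with the BO arm at its 5-replicate protocol and the random reference
  at 20 replicates — the null arm is computationally free, and a
  5-replicate reference would make the test power-limited by baseline
  noise rather than by the arms under study.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `k_context` | 5 | few-shot examples per prompt |
| `temperature` | 0.7 | completion sampling temperature |
| `n_completions` | 5 | samples per predictive distribution |
| `uncertainty_scale` | 5 | global sigma calibration factor |
| `lambda_mmr` / `subpool_size` | 0.5 / 10 | MMR trade-off and subpool size |
| `n_seed` | 2 | farthest-point seed experiments |
| `reducer.target_dim` | 32 | Isomap output dimension (GP arm) |

## Limitations

- The embedding geometry limits the GP arm's endgame: it reliably
  reaches the top half-percent of the pool but rarely the exact
  optimum, so its advantage over random search is clear but thinner
  than the (idealized) language-model arm's.
- Exact ties in acquisition scores resolve to lexicographic id — a
  reproducibility feature that becomes a visible deterministic scan
  when a surrogate's predictions are completely flat.
- No batching (one candidate per tell), no approximate nearest
  neighbors (exact search is the stated scope for pools up to 1e6),
  no isotonic or conformal recalibration, and no real API adapters in
  the test stack.
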