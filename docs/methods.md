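# Methods

This note defines the statistical models implemented in `netprior`, the
algorithmic and numerical choices that affect results, and the limits of the
synthetic validation protocol.

## Notation

A network over `m` nodes is a binary adjacency matrix `Ω ∈ {0,1}^{m×m}` with
zero diagonal; `Ω_ij = 1` means a directed edge `i → j`. An edge-confidence
source `k` is a matrix `Θ^k ∈ [0,1]^{m×m}` (zero diagonal) whose cell
`θ^k_ij` expresses how strongly source `k` believes in edge `i → j`. A
consensus prior `B ∈ [0,1]^{m×m}` collects per-edge beliefs `B_ij`.

All confidences are clipped into `[ε, 1−ε]` with `ε = 1e-6` before any
logarithm is taken (`clip_prior`); the closed-form combiners clip their
output the same way unless called with `clip=False`.

## Closed-form combiners (`netprior.combine`)

For `K` sources, cellwise:

- **NOM (Noisy-OR):** `B_ij = 1 − ∏_k (1 − θ^k_ij)`. With binary inputs and
  `clip=False` this is exactly the logical OR.
- **IP (independent product):** `B_ij = ∏_k θ^k_ij`.
- **MP (mean):** `B_ij = (1/K) Σ_k θ^k_ij`.

Since `∏ θ ≤ mean θ ≤ 1 − ∏(1−θ)` for values in [0,1], the combiners obey
`IP ≤ MP ≤ NOM` entry-wise (a tested invariant).

**Rank variants (`*.RNK`)** first replace every off-diagonal cell of each
source by its relative rank: average ranks over all `m(m−1)` off-diagonal
cells (ties get the mean rank), divided by the **maximum rank value**, so the
largest confidence maps to exactly 1 and an all-constant source maps to the
all-ones matrix. By default larger confidence ⇒ larger rank
(`direction="confidence_monotone"`); a `paper_descending` direction is
provided for sources whose raw values are distances rather than
confidences. The combiner is then applied to the rank matrices.

## Latent factor model (`netprior.lfm`)

The sources are modelled as conditionally independent noisy views of one
latent network `Ω`:

```
θ^k_ij | Ω_ij = 1  ~  Beta(α_k, 1)        (density α θ^{α−1})
θ^k_ij | Ω_ij = 0  ~  Beta(1, β_k)        (density β (1−θ)^{β−1})
Ω_ij               ~  Bernoulli(ρ),  ρ = 0.05 by default
```

`α_k, β_k` carry a flat prior on the log scale inside bounds
`[0.1, 1000]`. A sharp source has large `α_k, β_k`; a source that carries no
information is driven toward `α_k = β_k = 1`, i.e. the uniform density, which
removes its influence on the posterior over `Ω`. A `mirrored` likelihood
form (`Beta(α_k, β_k)` for present cells, `Beta(β_k, α_k)` for absent) is
also available.

The consensus prior is the matrix of posterior edge frequencies
`B_ij = P(Ω_ij = 1 | Θ^1..Θ^K)`, estimated by MCMC and clipped to
`[ε, 1−ε]`.

### Sampler

A Metropolis–Hastings chain over `(Ω, log α, log β)`:

- **Structure moves** (every iteration): uniform choice among all valid
  single-edge insertions, deletions and reversals; with `M(Ω) = m(m−1) + R`
  valid moves (`R` = number of reversible edges), the Hastings correction is
  `log M(Ω_old) − log M(Ω_new)`. Per-source sufficient statistics (sums of
  `log θ` and `log(1−θ)` over present cells) make each move O(K) via a
  precomputed per-cell log-posterior gain matrix.
- **Parameter moves** (every 10th iteration): a joint Gaussian proposal on
  `(log α, log β)` using a covariance adapted every 100 parameter moves from
  the most recent half of the parameter history, times a global scale that
  is driven toward a 0.234 acceptance rate by a multiplicative update
  `scale ← scale · exp(2(rate − 0.234))`, clipped to `[1e-6, 10]` and
  initialised at `2.38²/(2K)`. The windowed covariance plus the
  acceptance-targeted scale keeps the proposal matched to the posterior even
  when early burn-in (with a nearly empty `Ω`) lets the parameters wander
  through a flat likelihood region.

Defaults: `burn_in = 100_000`, `samples = 500_000`. Edge frequencies are
accumulated lazily (per-edge last-change bookkeeping), so one iteration is
O(1) beyond the move evaluation; 2×10⁵ iterations take ~1.5 s at m = 20,
K = 5 on one CPU core. An exact enumeration over all `2^{m(m−1)}` digraphs
(`exact_posterior_enumeration`, m ≤ 4) serves as the oracle for the chain.

## Bayesian network learning (`netprior.bn`)

Data are complete categorical samples. Structures are scored by BIC with
multinomial maximum-likelihood family terms:

```
score(G) = Σ_j [ logL̂(x_j | parents_j) − ½ log(n) (r_j − 1) q_j ] + log P(G)
```

where `r_j` is the number of categories of variable `j` and `q_j` the number
of parent configurations. The structure prior treats edges independently,
`P(G) ∝ ∏_{ij} B_ij^{Ω_ij} (1−B_ij)^{1−Ω_ij}`, which decomposes into
per-edge log-odds `log(B_ij/(1−B_ij))` plus a graph-independent constant;
`B ≡ 0.5` (or `prior=None`) reproduces plain BIC ranking.

Search:

- `exact_search` — Silander–Myllymäki dynamic programming (best parent set
  per subset, then sink-ordering DP), exact for m ≤ 14 under a
  `max_parents` cap; larger problems fall back to hill climbing.
- `hill_climb` — greedy add/delete/reverse with random restarts.
- `brute_force_search` — independent oracle enumerating all DAGs (m ≤ 5).

## Evaluation (`netprior.evaluation`)

`evaluation_curve` sweeps all cutoffs `c` in the set of unique prior values
plus `{0, 1+ulp}`, predicts edge `i → j` whenever `value_ij ≥ c`, and records
sensitivity/specificity over the `m(m−1)` ordered pairs. **oBAC** is the
maximum of `(sensitivity+specificity)/2` over the sweep. oBAC is invariant
under strictly monotone transformations of the values, and a constant prior
scores exactly 0.5 on any truth with at least one present and one absent
edge. `ignore_direction=True` collapses both matrices to skeletons (max over
each unordered pair) before sweeping — the appropriate view when comparing
structures learnable only up to Markov equivalence.

`path_explained_fraction` compares networks through directed reachability:
the *model view* is the fraction of inferred edges `i → j` with a directed
`i → j` path in the reference; the *knowledge view* is the fraction of
reference-connected ordered pairs preserved by the inferred network.
`paired_method_comparison` runs paired two-sided Wilcoxon signed-rank tests
over replicate score vectors (≥ 5 replicates) with Benjamini–Hochberg
correction.

## Synthetic validation protocol (`netprior.synthetic`)

- **Truth networks:** an undirected Barabási–Albert graph (default 2
  attachments per node, configurable) with uniformly random edge
  orientations stands in for a curated pathway collection; an `m`-node truth
  is the induced directed subgraph on the nodes visited by a random walk on
  the undirected skeleton (optionally resampled until acyclic).
- **Sources:** present cells drawn from `Beta(α_k, 1)`, absent cells from
  `Beta(1, β_k)` (matching the LFM likelihood); `noise_source` draws every
  cell from Uniform(0,1); `confidence_from_network_distance` maps
  shortest-path distances to confidences (inverse or exponential decay).
- **Data:** random conditional probability tables (Dirichlet(1) rows) on a
  DAG, sampled ancestrally.

What this protocol does **not** emulate: real knowledge sources are not
independent given the truth (databases share curation provenance), their
noise is not Beta-shaped, their coverage is incomplete rather than uniform,
and real regulatory relations are not faithfully multinomial. Results on
this generator validate the machinery, not biological performance.

## Numerical choices and conventions

- `ε = 1e-6` clipping before all logarithms; combiner outputs clipped unless
  `clip=False`.
- Matrix TSVs are written with 12 significant digits; round trips are exact
  to ~1e-11 relative error.
- All randomness flows through `numpy.random.Generator`; replicate seeds are
  spawned from a root `SeedSequence`, and derived integer seeds are kept
  below 2³¹. Identical seeds give bit-identical results, including the MCMC
  trace.
- Rank ties get average ranks; ranks are normalised by the maximum rank
  value.
- Cutoff grids use `value ≥ cutoff`; the grid always contains 0 (predict
  everything) and `1 + ulp` (predict nothing).
- Cholesky factorisation of the proposal covariance falls back to an
  identity-scaled proposal if the adapted covariance is not positive
  definite; a `1e-6` jitter is added on every adaptation.

## Problem sizes used in validation

| setting | value |
|---|---|
| MCMC-vs-enumeration oracle | m = 3, K = 2, 2×10⁵ iterations, 3 seeds |
| noise down-weighting | m = 20 (≈50 edges), K = 4+1, 3.5×10⁵ iterations, 10 replicates |
| prior recovery | m = 40, K = 5, 10 replicates |
| sample-size law | m = 10, 3 categories, max 3 parents, n ∈ {20, 50, 100, 5000} |
| search oracle | m = 4 (543 DAGs), 20 datasets |

## Limitations

- The per-edge-independent structure prior cannot express higher-order
  knowledge (mutual exclusivity, pathway membership constraints).
- Exact structure search is exponential in `m` (practical to m ≈ 14);
  beyond that only hill climbing is available.
- Edge directions within a Markov equivalence class are not identifiable
  from observational data; direction-aware accuracy comparisons against a
  prior therefore retain a persistent prior advantage at any sample size,
  which is why the sample-size analysis scores skeletons.
- LFM assumes sources are independent given the latent network and share a
  single global edge density ρ.
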