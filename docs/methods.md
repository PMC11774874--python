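# Methods

## Model

All statistics assume trait evolution by multivariate Brownian motion on
a rooted species phylogeny with branch lengths. For tips *i*, *j* the
trait covariance induced by shared ancestry is `C_ij`, the summed branch
length from the root to their most recent common ancestor; `C_ii` is the
root-to-tip depth. A *p*-trait system has `cov(vec X) = R ⊗ C`, with
**R** the *p × p* evolutionary rate matrix. Everything downstream is
generalized least squares with **C** as the error structure:

* GLS root means `a = (1'C⁻¹1)⁻¹ 1'C⁻¹X`;
* rate matrix `R = (X − 1a')'C⁻¹(X − 1a')/(n−1)` and its correlation
  scaling (phylogenetic Pearson correlations);
* PGLS: `β = (Z'C⁻¹Z)⁻¹Z'C⁻¹y`, `Z = [1, x]`, standard errors from
  `σ̂²(Z'C⁻¹Z)⁻¹` with `σ̂² = GLS RSS/(n−2)`, t and p on df = n−2
  (computed through statsmodels GLS);
* Blomberg's K = observed MSE₀/MSE divided by its Brownian expectation
  `(tr C − n/(1'C⁻¹1))/(n−1)`, where MSE uses `C⁻¹` and both mean-square
  errors center on the GLS mean. K = 1 identically on a star tree and in
  expectation under Brownian motion;
* Pagel's λ multiplies the off-diagonal of **C**; λ̂ maximizes the
  profile normal log-likelihood (GLS mean and σ² profiled analytically,
  σ̂² with the ML denominator *n*) over [0, λ_max] by bounded scalar
  search (tolerance 1e−8). λ_max = min(diag C)/max(offdiag C), the
  largest multiplier keeping the matrix positive semi-definite (≥ 1 for
  ultrametric trees), so estimates slightly above 1 are possible and are
  not clamped;
* phylogenetic PCA eigendecomposes **R** (covariance mode) or its
  correlation scaling (correlation mode, the default). In correlation
  mode loadings are trait–component correlations `V√d` (bounded by 1)
  and scores are GLS-centered, rate-standardized data projected on the
  eigenvectors. Axis signs are fixed so the largest-magnitude loading on
  each axis is positive.

Correlation significance uses the t-transform `t = r√((n−2)/(1−r²))`
with df = n−2 — the standard test for a Pearson correlation, applied
here to the phylogenetic correlations. |r| = 1 is mapped to p = 0
without a division error.

## Inference choices

* **λ = 0 boundary test.** The LR statistic against λ = 0 sits on the
  boundary of the parameter space, so the p-value uses the
  ½χ²₀ + ½χ²₁ mixture (half the χ²(1) tail, 1 when the LR is 0). Some
  reference implementations use the plain χ²(1) tail; that choice is
  conservative by a factor of 2 and does not change λ̂ or the
  log-likelihoods, which this package matches to reference software.
* **K permutation test.** Tip-to-value assignments are permuted
  (default 999 permutations, seed required);
  `p = (1 + #{MSE_perm ≤ MSE_obs})/(1 + n_perm)`. Lower phylogenetic MSE
  means stronger signal, so the test is one-sided against
  no-signal relabelings.
* **PGLS λ.** Fixed λ = 1 (plain Brownian errors) by default; `lam="ml"`
  profiles λ jointly with the regression.

## Numerical choices

* **C solves** go through Cholesky factorization. When the condition
  number exceeds 1e12 (e.g. zero-length terminal edges after polytomy
  resolution), a ridge of `1e−10 · mean(diag C)` is added once, with a
  warning; a matrix still singular after ridging raises.
* **Polytomy resolution** splits multifurcations deterministically in
  child input order with zero-length inserted edges. Since the inserted
  edges have length 0, root-to-MRCA path sums — and hence **C** and every
  downstream statistic — are invariant to the resolution; randomized
  resolution would change nothing.
* **Non-ultrametric trees** are accepted with a warning (validation
  checks structure, label uniqueness and non-negative lengths only).
* **Degenerate inputs**: constant traits raise for K; star trees raise
  for λ (unidentifiable); constant predictors raise in PGLS; all-zero
  paired differences give t = 0, p = 1, while nonzero zero-variance
  differences raise.

## Network stage

Edges are trait pairs with |r| > 0.5 **and** p < 0.05; weight is |r|,
sign kept as an attribute. Metrics:

* degree `k_i`, weighted degree (strength) `D_i = Σ_j a_ij`; hub traits
  are the argmax of D (all maxima on ties);
* betweenness with weighted shortest paths, **additive edge cost
  a_ij = |r|**, fractional counting over ties, normalized by
  `(n−1)(n−2)/2`;
* average path length = mean weighted shortest-path distance over
  unordered pairs (same |r| cost); reported as NaN with a
  `connected=False` flag when the graph is disconnected;
* edge density `L/(n(n−1)/2)`; clustering = global transitivity
  `3·triangles/connected triples` (unweighted, NaN for n < 3);
* connectance `L/(n(n+1)/2)`.

Two conventions here are reconstructions rather than textbook choices,
fixed by requiring internal consistency of the published values for this
system. A verbal definition of connectance ("fraction of links out of
all possible links") would duplicate edge density (18/36 = 0.5), yet the
published table prints 0.4 and 0.3 for the two networks; the
self-loop-inclusive denominator `n(n+1)/2` (18/45 = 0.4, 12/36 = 0.33)
is the unique simple denominator reproducing both. Likewise unweighted
hop-count path lengths would give 1.5/1.93, while the |r|-cost mean
shortest-path distance gives 1.076/1.272, matching the printed 1.1/1.3;
the |r| cost is used for betweenness too. With it, the recomputed
betweenness values also round to every printed per-trait entry. Note
that pricing an edge at |r| makes *stronger* correlations cost more,
so the convention is a reconstruction of how the published values were
produced, not a recommendation.

Report tables round half-up (ties away from zero) to one decimal,
matching the published display precision. The focal-trait comparison
pairs per-trait metrics over the traits present in both networks and
applies the paired t-test (df = shared − 1). At one-decimal precision
the degree row is integer-valued and exact, so its t statistic (4.58)
is recovered from recomputed metrics; weighted-degree and betweenness
t values from full-precision metrics differ in the second decimal from
those computed off the rounded printed rows (4.41 vs 4.28, −1.57 vs
−1.43). The comparison report therefore carries both: the
full-precision tests and `tests_at_report_precision`, where per-trait
metrics are first rounded to the display convention — the latter is what
values read off a printed table reproduce.

## Synthetic data

The generator emulates the study conditions: 32 tips (a seeded Yule tree
with birth rate 1, pendant edges extended by the memoryless waiting time
to the next speciation so no tip edge is zero), nine traits under
multivariate Brownian motion with λ_true = 1 and a correlation-scaled
rate matrix with two realistic blocks — a morphological
collaboration/conservation block (latent colM, RD, RTD, SRA, SRL, RDMC
with signs matching field expectations, e.g. RTD–RDMC 0.9, RTD–SRA
−0.85, colM–RD 0.75) and a chemical block (RNC, RC:N, RCC with the
RNC–RC:N trade-off at −0.8). The latent colonization trait is mapped
through a logistic (midpoint 0 = the Brownian root state, slope 1.5,
chosen so species-level colM spreads over most of (0, 100)%) and scaled
to a percentage; other traits are exponentiated so they are positive and
log-normal, matching the log transform applied at ingestion.

What the generator does **not** emulate: intraspecific replication and
measurement error, site-level environmental gradients, non-Brownian
evolution (selection regimes, rate shifts), or the discreteness of
segment-level colonization scoring in the species-level table. Passing
recovery tests therefore show the estimators are correct for their own
generative model, not that the model is adequate for any particular
field dataset.

Raw-measurement helpers implement the trait definitions directly:
SRL = L/DW (m/g), RTD = DW/V (g/cm³), SRA = S/DW (cm²/g),
RDMC = 1000·DW/FW (mg/g); colonization scoring assigns
100/len(segments) percent per colonized segment — 10% each with the
standard ten scored segments (other counts warn and generalize
proportionally).

## Fixtures

The published 9×9 correlation matrix ships with its printed significance
marks; the loader materializes indicator p-values (0.01 for marked
pairs, 0.5 otherwise) so the standard retention rule reproduces the
printed networks. These placeholders are *not* the study's p-values —
the underlying 32-species trait table is unpublished, which is also why
the printed correlation values, the pPCA variance proportions and the
PGLS fit against colM are validated structurally and by parameter
recovery rather than numerically.

## Problem sizes in the test suite

Recovery experiments run at: λ truth 1 — 200 replicates × 100 tips;
λ truth 0 — 200 × 50; Blomberg K under Brownian motion — 1000 × 50
(mean), 200 × 50 (null calibration at 199 permutations); rate-matrix
recovery — 500 trait replicates on one 200-tip tree; PGLS slope — 200 ×
100; block-structure recovery — 100 replicates × 200 tips. Brute-force
path enumeration validates every network metric on random graphs of 4–8
nodes. The full suite runs in about a minute on one core.

## Known limitations

* Single-predictor PGLS only; no Ornstein–Uhlenbeck or multi-rate
  models, no ancestral-state reconstruction.
* The correlation significance t-transform is a modeling choice; with
  GLS-estimated correlations it is approximate, not exact.
* λ̂ > 1 is reported when the likelihood favors it (up to λ_max); users
  wanting the conventional [0, 1] range should truncate downstream.
* Network comparison assumes the same retention rule on both networks
  and ignores the dependence between the two networks' metrics beyond
  pairing by trait.
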