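# Methods

This note documents the statistical models, algorithms, numerical choices
and limitations of `seqpower`.  Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and design

The package evaluates bulk RNA-seq experimental designs by resampling pilot
count data and rerunning a complete DE analysis on every resample.  Three
sampling devices (replicate subsetting, count thinning, pseudo-replicate
simulation), one DE engine (TMM + conditional-likelihood NB dispersion +
exact test + BH), and a set of evaluation indicators (counts, stability,
power, TPR/FPR, ROC-optimal thresholds) are composed by two orchestrators:
the replicate × depth grid and the pseudo-replicate meta surface.  The
engine interface (`run_de(matrix, design, pair, params) -> DEResult`) is
deliberately narrow so alternative engines could be plugged in; only the
native exact-test engine ships.

## Synthetic pilot generator

`generate_pilot` emulates a two-condition plant bulk RNA-seq pilot.

- Relative abundances `q_g ~ LogNormal(0, 2)` (natural-log scale).  The
  heavy right tail reproduces the strong expression skew of real libraries.
- A gene is DE with probability `pi_de` (default 0.5, mirroring a pilot in
  which roughly half the transcriptome responds between two developmental
  stages).  True log2 fold changes have a random, balanced sign and a
  zero-truncated normal magnitude: `|lfc| ~ N(0, lfc_sd²)` conditioned on
  `|lfc| ≥ lfc_min`, with `lfc_sd = 1` and `lfc_min = 0.25` so "DE" is never
  degenerate.
- The effect is split symmetrically across conditions (`2^{±lfc/2}`), so the
  grand-mean abundance is effect-free and composition bias stays small; TMM
  correctness is tested separately with deliberately biased columns.
- Gene-wise dispersions `φ_g ~ Gamma(shape 2, scale 0.025)` (mean 0.05),
  typical of plant bulk RNA-seq; `constant_dispersion` overrides the gamma
  draw for parameter-recovery and null-calibration experiments.
- Counts are gamma-Poisson (NB) draws with expected column sums equal to the
  target library size; per-condition normalizers make the expectation exact.

Defaults (20,000 genes, 8 replicates/condition, 5 M reads/sample) are the
study-scale conditions; unit tests shrink genes and reads, not structure.

What the generator does *not* emulate: GC/length bias, outlier samples,
batch effects, correlated genes, or unequal realized library sizes beyond
Poisson-level noise.  Passing tests therefore demonstrate correctness of the
machinery and the qualitative design trade-offs under a clean NB world, not
performance guarantees on any particular real data set.

`empirical_lfc_check` is the generator's calibration harness: the naive
normalized log-ratio of condition means must recover true fold changes to
< 0.1 log2 units in the Poisson/deep-library limit and < 0.25 under default
noise.

## Resampling devices

- **Replicate subsetting** draws `r` samples per condition uniformly without
  replacement, independently per condition (the joint allocation across
  conditions is not constrained).
- **Thinning** to depth `d` is a multivariate hypergeometric draw over genes
  per column — the count-level equivalent of drawing reads without
  replacement.  It preserves expectations (`E = y · d/N`), enforces exact
  column totals, and is consistent under composition (thinning to `d` then
  `d' < d` is distributed as thinning to `d'` directly).  Columns at or
  below the target pass through with a logged warning.
- **Pseudo-replicates** draw independent U(0,1) coefficients over the source
  replicates, normalize them to sum to 1, and sample
  `Multinomial(target, Σ_k w_k p_gk)`.  Normalized-uniform weights were
  chosen as the simplest reading of "uniform random coefficients"; a
  symmetric Dirichlet would be a drop-in replacement and is isolated in one
  line.
  Expected weights are 1/k, so pseudo-replicate means average the sources.

Every stochastic stage takes a generator derived from
`SeedSequence(master_seed, spawn_key=(stage_tag, indices...))`; there is no
global RNG state, cells of a grid are order-independent, and any cell can be
recomputed in isolation.

## The DE engine

**TMM.**  Reference sample: 75th-percentile CPM closest to the mean of those
percentiles.  For sample *j* vs reference *rf*, over genes positive in both:
`M_g = log2((y_gj/N_j)/(y_grf/N_rf))`, `A_g = ½ log2` of the product of the
two proportions.  The 30% most extreme M and 5% most extreme A are trimmed
from **each** tail; the factor is `2^{Σ w M / Σ w}` with
`w = 1/((N_j−y_j)/(N_j y_j) + (N_rf−y_rf)/(N_rf y_rf))` (inverse asymptotic
binomial variance).  Factors are rescaled to geometric mean 1.  Fewer than
10 surviving genes triggers a factor-1 fallback with a warning.

**Pseudo-counts.**  Dispersion estimation and the exact test operate on
counts deterministically rescaled to the geometric-mean effective library
size and rounded to integers.  This is an intentional simplification of
edgeR's quantile-based pseudo-count adjustment: it is fully specifiable and
testable, at the cost of exact agreement with any particular edgeR version
(the cross-check test shows the practical difference is negligible).

**Dispersion.**  For a replicate group of size *n* with counts `y_i`, sum
`s`, and `k = 1/φ`, the conditional log-likelihood (terms constant in φ
dropped) is `Σ_i lgamma(y_i + k) − n·lgamma(k) + lgamma(nk) − lgamma(s +
nk)`.  The common estimate maximizes the sum over genes and groups by 1-D
bounded search on log φ over [1e-6, 10] with tolerance 1e-4 (log-space);
estimates within tolerance of a bound snap to it.  Tagwise estimates
maximize `CLL_g(φ) + w · mean_g' CLL_g'(φ)` with prior weight `w` in
pseudo-gene units (default 10): a coarse 121-point log-grid scan brackets
each gene's optimum (and provides the pooled term, interpolated by a cubic
spline), and vectorized golden-section search refines all genes
simultaneously.  `w → ∞` collapses every gene to the common value; `w = 0`
matches an independent per-gene grid-search oracle.

**Mode rule.**  Groups of ≤ 4 replicates use the common dispersion only
(per-gene estimates are too unstable); larger groups use tagwise estimates.
The mode actually used is recorded in the result provenance.

**Exact test.**  Sums of *n* iid NB(μ, φ) are NB with size `n/φ`.
Conditional on the two-group total `s`, the group-A sum follows a negative
hypergeometric law with parameters `r_A = n_A/φ`, `r_B = n_B/φ`:

    P(a | s) ∝ C(a + r_A − 1, a) · C(s − a + r_B − 1, s − a),

normalized in closed form via the Vandermonde identity (no summation pass is
needed).  In the Poisson limit (`φ < 1e-10`) the conditional law is
`Binomial(s, n_A/(n_A+n_B))`.  The two-sided p-value sums the probabilities
of all partitions at most as probable as the observed one, with relative tie
tolerance 1e-12.  Enumeration is exact and O(s) per gene, vectorized across
genes in blocks of ≤ 8M partitions to bound memory; shared log-gamma lookup
tables cover the common-dispersion case.  Every floating-point expression is
grouped symmetrically so that swapping the condition labels gives bitwise
identical p-values (near-modal partitions would otherwise flip across the
tie boundary).  Genes with zero total get p = 1 and logFC = 0 by contract.
`logFC = log2((s_B/n_B + ½)/(s_A/n_A + ½))` — second condition over first,
prior 0.5 per group mean to avoid infinities.

**BH.**  Standard step-up on the raw p-values of *all* genes (no filtering
anywhere in the pipeline), capped at 1, returned in input order.

### Null calibration

Because the test conditions on discrete sums, raw null p-values are
conservative, never anti-conservative — verified on Poisson data with
supplied φ = 0.  With *estimated* dispersions and heterogeneous gene-wise
φ_g, shrinkage under-corrects the upper tail of the φ distribution, so
occasional false BH rejections occur: a gene whose true dispersion sits far
above the common value can show a chance two-fold difference that looks
significant under its shrunk estimate.  This is a property of
common/shrunk-dispersion exact tests generally, and is exactly the behavior
the mock within-condition experiment measures.  At study scale (20,000
genes, 5 vs 5 replicates, BH 0.01) the mock FPR stays within a few 1e-4 per
split — of the order of one gene in 20,000 — and is exactly 0 in every
split when the null condition is generated with a constant (correctly
specified) dispersion.

## Indicators and thresholds

All declarations use strict inequality (`padj < α`), with α = 0.05 for
routine DE, 1e-4 for the power reference list, 1e-3 for the TPR/FPR truth
list, and 0.01 for FPR experiments.  In mock within-condition comparisons
the FPR divides by all genes (every declaration is false there); in
truth-based comparisons it divides by the non-truth universe.  Expression
strata split genes at the interpolated quartiles of mean logCPM (low < Q1 <
medium < Q3 < high, strict); stratum-restricted indicators intersect both
the declared sets and the reference with the stratum before computing.

Mock splits use two *disjoint* groups per split (no sample reuse within a
split); the allocation across splits is independent.

## ROC-optimal thresholds and the 2^−r rule

The ROC curve sweeps the declared set `{g : padj < t}` over the sorted
distinct adjusted p-values augmented with decade-style values and endpoints.
The optimal threshold maximizes Youden's J = TPR − FPR, ties broken toward
the smallest threshold; "closest to the (0,1) corner" is available as an
alternative criterion.  Youden's J was chosen because the quantity of
interest is the trade-off point where additional true positives stop paying
for additional false positives.  Per replicate number, the reported optimum
is the median over the repetition block (30 subsamples by default); the
2^−r relationship is summarized by an OLS fit of log2(threshold) on r
(slope −1, intercept 0 corresponds exactly to 2^−r).

## Meta-analysis stage

Contrast descriptors (distance between condition means, pooled gene
variance) are computed on logCPM so they are comparable across depths; the
replicate number is the rounded mean of the two group sizes (half away from
zero).  The simulated surface builds *all* replicates of both conditions as
pseudo-replicates (no mixing of real and simulated samples in one analysis)
and records the DE count at α = 0.05 per (pair, r, library size,
repetition).  Level binning for descriptor summaries uses terciles.

## Problem sizes

Unit tests run on hundreds of genes and 10⁴–10⁵ reads; the study-scale
checks (acceptance script and end-to-end tests) use 20,000 genes, 8+8 or 12
replicates, 5 M reads/sample, 30 repetitions — sizes chosen so a complete
run finishes in minutes on a single core while keeping per-gene counts in
the regime where the exact test's discreteness no longer dominates.

## Known limitations

- Exact replication of any edgeR version is a non-goal; pseudo-count
  construction and tagwise shrinkage differ in detail (behavioral agreement
  is enforced by the cross-check tests).
- Only two-group contrasts; no GLM/quasi-likelihood path, no multi-factor
  designs, no covariates.
- Count-level thinning cannot reproduce read-level artifacts (mapping
  ambiguity, duplication structure) of read-level down-sampling.
- The generator's clean NB world understates real biological and technical
  heterogeneity; absolute indicator values on real data will differ even
  when the qualitative replicate-vs-depth trade-offs hold.
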