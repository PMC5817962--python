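# seqpower

**Replicate-number and sequencing-depth design evaluation for bulk RNA-seq
differential-expression studies.**

How many biological replicates, and how many reads per sample, does a
differential-expression (DE) study need?  `seqpower` answers this from pilot
count data (real or synthetic): it repeatedly subsamples replicates and thins
libraries, reruns a complete DE analysis on every subsample, and measures how
the number of DE genes, their *stability* across subsamples, statistical
power, and the false positive rate respond to the design.  It also extracts
the ROC-optimal FDR threshold per replicate number — which empirically tracks
**2^−r**, where *r* is the replicate number — and simulates pseudo-replicates
for meta-analysis-style what-if designs.

It is aimed at bioinformaticians and statisticians planning bulk RNA-seq
experiments (the presets emulate a plant two-condition pilot with eight
replicates per condition), and at methodologists studying DE-analysis
behavior under resampling.

## The model and the statistics

Counts for gene *g* in sample *j* are modeled as negative binomial with mean
*μ_gj* and variance *μ(1 + μφ_g)*, where *φ_g* is the gene-wise dispersion.
The built-in DE engine mirrors the classical exact-test pipeline:

- **TMM normalization** — trimmed mean of M-values against a reference
  sample, inverse-asymptotic-variance weights; factors rescaled to geometric
  mean 1.
- **Dispersion** — maximum conditional likelihood on pseudo-counts equalized
  to a common library size.  A single common *φ* is used when the smaller
  group has ≤ 4 replicates; otherwise per-gene ("tagwise") estimates shrink
  toward the pooled likelihood with a weighted-likelihood prior.
- **Exact test** — within-group sums are NB; conditional on the two-group
  total the group-A sum is negative hypergeometric (binomial in the Poisson
  limit).  The two-sided p-value is the total probability of all partitions
  at most as probable as the observed one, enumerated exactly.
- **Benjamini–Hochberg** step-up FDR adjustment; a gene is DE when
  `padj < α` (strict).

Design indicators, per (replicate number *r*, depth *d*) cell over repeated
subsamples: median number of DE genes; **stability** (genes common to all
repetitions); **power** (fraction of a stringent full-data reference list,
`padj < 1e-4`, that is recovered); TPR/FPR/TNR against an estimated truth
list (`padj < 0.001` on full data); and ROC curves over the FDR-threshold
grid with Youden-optimal thresholds.

The engine is cross-validated against edgeR in the test suite (TMM factors,
common dispersion and exact-test p-values agree to within small tolerances).

## Worked example

```python
from seqpower import *

spec = PilotSpec(n_genes=2000, replicates_per_condition=8,
                 target_library_size=500_000, pi_de=0.5, seed=0)
matrix, design, truth = generate_pilot(spec)

full = run_de(matrix, design, ("A", "B"))
reference = reference_de_set(full, alpha_reference=1e-4)
print(f"reference list (padj < 1e-4, full data): {len(reference)} genes")

params = AnalysisParams(replicate_grid=(2, 4, 6), depth_grid=(100_000, 400_000),
                        n_repetitions=10, master_seed=0)
cells = run_grid(matrix, design, params, ("A", "B"))
summary = aggregate_indicators(cells, reference)
print(summary[["median_nde", "stability_nde", "median_power", "stability_power"]].round(3))

truth_genes = truth_de_set(full, 1e-3)
profile = replicate_threshold_profile(matrix, design, ("A", "B"), truth_genes,
                                      r_values=(2, 4, 6), n_repetitions=10, seed=0)
slope, _ = fit_threshold_vs_replicates(list(profile.items()))
print("optimal BH thresholds:", {r: round(t, 4) for r, t in profile.items()})
print(f"slope of log2(threshold) vs r: {slope:.2f}")
```

Output:

```
reference list (padj < 1e-4, full data): 388 genes
          median_nde  stability_nde  median_power  stability_power
r depth
2 100000       147.5             35         0.343            0.090
  400000       287.5            123         0.634            0.317
4 100000       299.5            150         0.662            0.387
  400000       492.0            282         0.946            0.722
6 100000       401.0            233         0.821            0.582
  400000       597.5            449         0.997            0.987
optimal BH thresholds: {2: 0.3071, 4: 0.0848, 6: 0.0133}
slope of log2(threshold) vs r: -1.13
```

Reading it: power and stability both rise with replicates and depth, but the
stability indicators rise faster with replicates — at a fixed read budget,
replicates beat depth.  With two replicates the median analysis recovers 34%
of the reference list at 100k reads, but only 9% of it survives all ten
subsamples.  The ROC-optimal BH threshold falls from ~0.31 at *r* = 2 to
~0.013 at *r* = 6; the fitted slope of log2(threshold) against *r* is close
to −1, i.e. the optimum behaves like 2^−r — an arbitrary 5% cutoff is far
from optimal at small *r*.

The same stages are exposed as a CLI: `seqpower simulate | de | grid | roc |
mock-fpr | meta` (see `seqpower --help`).

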