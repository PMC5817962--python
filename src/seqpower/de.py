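"""Negative-binomial differential-expression engine.

A self-contained exact-test pipeline for two-group count comparisons:

1. TMM normalization (trimmed mean of M-values against a reference sample,
   inverse-asymptotic-variance weights);
2. pseudo-counts equalized to a common library size;
3. negative-binomial dispersion by maximum conditional likelihood — a single
   common value, optionally shrunk per-gene ("tagwise") through a
   weighted-likelihood pull toward the pooled likelihood;
4. a sum-conditioned exact test: within-group sums are NB, and conditional on
   the two-group total the p-value is the total probability of all partitions
   at most as probable as the observed one;
5. Benjamini-Hochberg step-up adjustment.

The conditional law of the group-A sum given the total is negative
hypergeometric with shape parameters ``n_A/phi`` and ``n_B/phi`` (binomial in
the Poisson limit ``phi -> 0``), which this module evaluates in closed form
and enumerates exactly, in blocks, for every gene.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import rankdata

from .data_model import AnalysisParams, CountMatrix, DEResult, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "NormalizationFactors",
    "DispersionEstimates",
    "tmm_factors",
    "log_cpm",
    "estimate_common_dispersion",
    "estimate_tagwise_dispersion",
    "exact_test",
    "bh_adjust",
    "run_de",
    "DISPERSION_BOUNDS",
]

#: Search bounds for the dispersion maximization (phi scale).
DISPERSION_BOUNDS = (1e-6, 10.0)
#: Tolerance of the dispersion maximization, in log-phi space.
DISPERSION_LOG_TOL = 1e-4
#: Replicate groups of this size or smaller use the common dispersion only.
COMMON_DISPERSION_MAX_REPLICATES = 4
#: Prior count per group mean when forming log fold changes.
LOGFC_PRIOR = 0.5


@dataclass(frozen=True)
class NormalizationFactors:
    """Per-sample TMM scale factors with geometric mean one."""

    sample_ids: tuple[str, ...]
    factors: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.factors, dtype=float)
        n = np.asarray(self.library_sizes, dtype=float)
        if f.shape != (len(self.sample_ids),) or n.shape != f.shape:
            raise ValueError("factor arrays must match sample_ids length")
        if (f <= 0).any():
            raise ValueError("normalization factors must be positive")
        if abs(np.mean(np.log(f))) > 1e-9:
            raise ValueError("normalization factors must have geometric mean 1")
        f.setflags(write=False)
        n.setflags(write=False)
        object.__setattr__(self, "factors", f)
        object.__setattr__(self, "library_sizes", n)

    def effective_sizes(self) -> np.ndarray:
        """Effective library sizes: column sum times scale factor."""
        return self.library_sizes * self.factors


@dataclass(frozen=True)
class DispersionEstimates:
    """Common and (optionally) per-gene tagwise NB dispersions."""

    common: float
    tagwise: np.ndarray | None
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in ("common", "tagwise"):
            raise ValueError("mode must be 'common' or 'tagwise'")
        if not (0.0 <= self.common <= DISPERSION_BOUNDS[1]):
            raise ValueError("common dispersion out of range")
        if self.mode == "tagwise":
            if self.tagwise is None:
                raise ValueError("tagwise mode requires per-gene dispersions")
            tw = np.asarray(self.tagwise, dtype=float)
            if (tw < 0).any() or (tw > DISPERSION_BOUNDS[1]).any():
                raise ValueError("tagwise dispersions out of range")
            tw.setflags(write=False)
            object.__setattr__(self, "tagwise", tw)

    def per_gene(self, n_genes: int) -> np.ndarray:
        if self.mode == "tagwise":
            if len(self.tagwise) != n_genes:
                raise ValueError("tagwise dispersion length mismatch")
            return self.tagwise
        return np.full(n_genes, float(self.common))


def tmm_factors(
    matrix: CountMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    min_genes: int = 10,
    ref_sample: str | None = None,
) -> NormalizationFactors:
    """Trimmed-mean-of-M-values scale factors.

    The reference is the sample whose 75th-percentile CPM is closest to the
    mean of those percentiles.  For each other sample, per-gene log-ratios
    ``M`` and average log-abundances ``A`` are computed over genes positive in
    both samples; the ``trim_m`` most extreme fraction of M and ``trim_a`` of
    A are dropped from each tail; the factor is two to the weighted mean of
    the surviving M, weighted by inverse asymptotic binomial variance.
    Factors are rescaled to geometric mean one.  If fewer than ``min_genes``
    genes survive trimming, the factor falls back to one with a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    counts = matrix.counts
    lib = matrix.library_sizes().astype(float)
    if (lib == 0).any():
        raise ValueError("TMM cannot normalize an all-zero sample")
    cpm = counts / lib * 1e6
    p75 = np.quantile(cpm, 0.75, axis=0)
    if ref_sample is None:
        ref = int(np.argmin(np.abs(p75 - p75.mean())))
    else:
        ref = matrix.sample_index(ref_sample)

    yr = counts[:, ref].astype(float)
    nr = lib[ref]
    factors = np.ones(matrix.n_samples)
    for j in range(matrix.n_samples):
        if j == ref:
            continue
        yj = counts[:, j].astype(float)
        nj = lib[j]
        pos = (yj > 0) & (yr > 0)
        if not pos.any():
            logger.warning("no genes shared by %s and the reference; factor 1", matrix.sample_ids[j])
            continue
        pj = yj[pos] / nj
        pr = yr[pos] / nr
        m = np.log2(pj / pr)
        a = 0.5 * np.log2(pj * pr)
        w = 1.0 / ((nj - yj[pos]) / (nj * yj[pos]) + (nr - yr[pos]) / (nr * yr[pos]))
        n = m.size
        rm = rankdata(m)
        ra = rankdata(a)
        keep = (
            (rm > n * trim_m)
            & (rm <= n * (1.0 - trim_m))
            & (ra > n * trim_a)
            & (ra <= n * (1.0 - trim_a))
        )
        if keep.sum() < min_genes:
            logger.warning(
                "only %d genes survive TMM trimming for %s; factor set to 1",
                int(keep.sum()),
                matrix.sample_ids[j],
            )
            continue
        factors[j] = 2.0 ** (np.sum(w[keep] * m[keep]) / np.sum(w[keep]))

    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(matrix.sample_ids, factors, lib)


def log_cpm(
    matrix: CountMatrix,
    factors: NormalizationFactors,
    prior_count: float = 0.5,
) -> np.ndarray:
    """log2 counts-per-million on effective library sizes, with a prior count.

    ``logCPM_gj = log2((y_gj + prior) / (N_j f_j + 2 prior) * 1e6)``.
    """
    if factors.sample_ids != matrix.sample_ids:
        raise ValueError("normalization factors do not match the matrix samples")
    eff = factors.effective_sizes()
    return np.log2((matrix.counts + prior_count) / (eff + 2.0 * prior_count) * 1e6)


# ---------------------------------------------------------------------------
# dispersion estimation
# ---------------------------------------------------------------------------


def _group_columns(matrix: CountMatrix, design: StudyDesign) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for cond in design.conditions:
        cols = [matrix.sample_index(s) for s in design.samples(cond) if s in matrix.sample_ids]
        if cols:
            groups[cond] = cols
    return groups


def _pseudo_counts(matrix: CountMatrix, factors: NormalizationFactors) -> np.ndarray:
    """Counts rescaled to a common effective library size (geometric mean)."""
    eff = factors.effective_sizes()
    common = np.exp(np.mean(np.log(eff)))
    return np.rint(matrix.counts * (common / eff)).astype(np.int64)


def _cond_loglik(
    pseudo: np.ndarray,
    group_cols: Sequence[Sequence[int]],
    phi: np.ndarray | float,
) -> np.ndarray:
    """Per-gene NB conditional log-likelihood, summed over replicate groups.

    For a group of ``n`` equal-mean NB(mu, phi) counts ``y_i`` with sum ``s``,
    the likelihood of the counts conditional on ``s`` (terms constant in phi
    dropped) is ``sum_i lgamma(y_i + k) - n lgamma(k) + lgamma(n k) -
    lgamma(s + n k)`` with ``k = 1/phi``.
    """
    k = 1.0 / np.asarray(phi, dtype=float)
    per_gene = k if k.ndim == 1 else None
    total = np.zeros(pseudo.shape[0])
    for cols in group_cols:
        n = len(cols)
        if n < 2:
            continue
        y = pseudo[:, list(cols)]
        s = y.sum(axis=1)
        kk = k[:, None] if per_gene is not None else k
        total += (
            gammaln(y + kk).sum(axis=1)
            - n * gammaln(k)
            + gammaln(n * k)
            - gammaln(s + n * k)
        )
    return total


def _replicated_groups(matrix: CountMatrix, design: StudyDesign) -> list[list[int]]:
    groups = [cols for cols in _group_columns(matrix, design).values() if len(cols) >= 2]
    if not groups:
        raise ValueError("dispersion estimation needs a condition with >= 2 replicates")
    return groups


def estimate_common_dispersion(
    matrix: CountMatrix,
    design: StudyDesign,
    factors: NormalizationFactors,
    bounds: tuple[float, float] = DISPERSION_BOUNDS,
    tol: float = DISPERSION_LOG_TOL,
) -> float:
    """Common NB dispersion maximizing the summed conditional log-likelihood.

    One-dimensional bounded maximization on the log-phi scale over ``bounds``;
    estimates within tolerance of a bound are snapped to it.
    """
    groups = _replicated_groups(matrix, design)
    pseudo = _pseudo_counts(matrix, factors)
    lo, hi = math.log(bounds[0]), math.log(bounds[1])

    def neg(x: float) -> float:
        return -float(_cond_loglik(pseudo, groups, math.exp(x)).sum())

    res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": tol})
    x = float(res.x)
    if x - lo < 10 * tol and neg(lo) <= neg(x) + 1e-9:
        x = lo
    elif hi - x < 10 * tol and neg(hi) <= neg(x) + 1e-9:
        x = hi
    return float(math.exp(x))


def _golden_max(f, lo: np.ndarray, hi: np.ndarray, iters: int = 45) -> np.ndarray:
    """Vectorized golden-section maximization of f over per-element brackets."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo.astype(float).copy(), hi.astype(float).copy()
    for _ in range(iters):
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = f(c), f(d)
        right = fc < fd
        a = np.where(right, c, a)
        b = np.where(right, b, d)
    return (a + b) / 2.0


def estimate_tagwise_dispersion(
    matrix: CountMatrix,
    design: StudyDesign,
    factors: NormalizationFactors,
    phi_common: float,
    prior_weight: float = 10.0,
    bounds: tuple[float, float] = DISPERSION_BOUNDS,
    n_grid: int = 121,
) -> np.ndarray:
    """Per-gene dispersions shrunk toward the pooled conditional likelihood.

    Each gene maximizes its own conditional log-likelihood plus
    ``prior_weight`` times the across-gene average conditional log-likelihood
    (a weighted-likelihood pull toward the common value, ``prior_weight`` in
    pseudo-gene units).  A coarse log-grid scan brackets each gene's maximum;
    golden-section search refines it, with the pooled term interpolated by a
    cubic spline of the grid values.
    """
    if prior_weight < 0:
        raise ValueError("prior_weight must be >= 0")
    groups = _replicated_groups(matrix, design)
    pseudo = _pseudo_counts(matrix, factors)
    G = matrix.n_genes
    lo, hi = math.log(bounds[0]), math.log(bounds[1])
    xgrid = np.linspace(lo, hi, n_grid)

    cll_grid = np.empty((G, n_grid))
    for i, x in enumerate(xgrid):
        cll_grid[:, i] = _cond_loglik(pseudo, groups, math.exp(x))
    shared = cll_grid.mean(axis=0)
    shared_spline = CubicSpline(xgrid, shared)

    objective_grid = cll_grid + prior_weight * shared
    best = objective_grid.argmax(axis=1)
    lo_idx = np.maximum(best - 1, 0)
    hi_idx = np.minimum(best + 1, n_grid - 1)

    def f(x: np.ndarray) -> np.ndarray:
        return _cond_loglik(pseudo, groups, np.exp(x)) + prior_weight * shared_spline(x)

    x_opt = _golden_max(f, xgrid[lo_idx], xgrid[hi_idx])
    x_opt = np.where(x_opt - lo < 10 * DISPERSION_LOG_TOL, lo, x_opt)
    x_opt = np.where(hi - x_opt < 10 * DISPERSION_LOG_TOL, hi, x_opt)
    return np.exp(x_opt)


# ---------------------------------------------------------------------------
# exact test
# ---------------------------------------------------------------------------

#: Relative tolerance for "probability <= observed" ties in the enumeration.
TIE_RTOL = 1e-12
#: Maximum number of enumerated partitions held in memory at once.
BLOCK_ELEMS = 8_000_000


def _blocks(s: np.ndarray, block_elems: int):
    """Yield slices of the gene axis whose enumeration sizes fit in a block."""
    start = 0
    total = 0
    for g in range(len(s)):
        size = int(s[g]) + 1
        if total and total + size > block_elems:
            yield slice(start, g)
            start = g
            total = 0
        total += size
    if start < len(s):
        yield slice(start, len(s))


def exact_nb_pvalues(
    s_a: np.ndarray,
    s_b: np.ndarray,
    n_a: int,
    n_b: int,
    phi: np.ndarray | float,
    tie_rtol: float = TIE_RTOL,
    block_elems: int = BLOCK_ELEMS,
) -> np.ndarray:
    """Two-sided exact-test p-values for group sums ``(s_a, s_b)``.

    Group sums of ``n`` iid NB(mu, phi) counts are NB with size ``n/phi``;
    conditional on the total ``s = s_a + s_b`` the group-A sum follows a
    negative hypergeometric law with parameters ``n_a/phi`` and ``n_b/phi``
    (binomial with success probability ``n_a/(n_a+n_b)`` in the Poisson
    limit).  The p-value is the total conditional probability of all
    partitions ``(a, s-a)`` whose probability is at most that of the observed
    one, up to relative tolerance ``tie_rtol`` for floating-point ties.
    Enumeration is exact and vectorized; genes are processed in blocks of at
    most ``block_elems`` partitions.  Genes with zero total get p = 1.
    """
    s_a = np.asarray(s_a, dtype=np.int64)
    s_b = np.asarray(s_b, dtype=np.int64)
    G = len(s_a)
    phi_arr = np.broadcast_to(np.asarray(phi, dtype=float), (G,))
    s = s_a + s_b
    pvals = np.ones(G)
    active = s > 0
    if not active.any():
        return pvals
    tie_eps = math.log1p(tie_rtol)

    max_s = int(s.max())
    t_fact = gammaln(np.arange(max_s + 1, dtype=float) + 1.0)  # gammaln(x+1) table

    poisson = active & (phi_arr < 1e-10)
    nb = active & ~poisson

    # --- Poisson limit: conditional law Binomial(s, n_a / (n_a + n_b)) -----
    if poisson.any():
        idx_all = np.flatnonzero(poisson)
        p_bin = n_a / (n_a + n_b)
        logp, logq = math.log(p_bin), math.log(1.0 - p_bin)
        for sl_genes in _blocks(s[idx_all], block_elems):
            gsel = idx_all[sl_genes]
            ss, aa_obs = s[gsel], s_a[gsel]
            lengths = ss + 1
            idx = np.repeat(np.arange(len(gsel)), lengths)
            offsets = np.concatenate(([0], np.cumsum(lengths)))[:-1]
            a = np.arange(lengths.sum()) - offsets[idx]
            sa_rep = ss[idx]
            # symmetric grouping: bitwise invariant under swapping the labels
            logw = (a * logp + (sa_rep - a) * logq) - (t_fact[a] + t_fact[sa_rep - a])
            obs = (aa_obs * logp + (ss - aa_obs) * logq) - (
                t_fact[aa_obs] + t_fact[ss - aa_obs]
            )
            mask = logw <= obs[idx] + tie_eps
            # normalizer: sum_a w(a) = 1 / s!
            pmf = np.exp(logw + t_fact[ss][idx])
            pvals[gsel] = np.bincount(idx, np.where(mask, pmf, 0.0), minlength=len(gsel))

    # --- Negative binomial: negative hypergeometric conditional law --------
    if nb.any():
        idx_all = np.flatnonzero(nb)
        scalar_phi = np.unique(phi_arr[idx_all]).size == 1
        if scalar_phi:
            r_a = n_a / phi_arr[idx_all[0]]
            r_b = n_b / phi_arr[idx_all[0]]
            t_a = gammaln(np.arange(max_s + 1, dtype=float) + r_a)
            t_b = gammaln(np.arange(max_s + 1, dtype=float) + r_b)
        for sl_genes in _blocks(s[idx_all], block_elems):
            gsel = idx_all[sl_genes]
            ss, aa_obs = s[gsel], s_a[gsel]
            ra_g = n_a / phi_arr[gsel]
            rb_g = n_b / phi_arr[gsel]
            lengths = ss + 1
            idx = np.repeat(np.arange(len(gsel)), lengths)
            offsets = np.concatenate(([0], np.cumsum(lengths)))[:-1]
            a = np.arange(lengths.sum()) - offsets[idx]
            sa_rep = ss[idx]
            # symmetric groupings keep every expression bitwise invariant
            # under swapping the two condition labels
            if scalar_phi:
                logw = (t_a[a] + t_b[sa_rep - a]) - (t_fact[a] + t_fact[sa_rep - a])
                obs = (t_a[aa_obs] + t_b[ss - aa_obs]) - (
                    t_fact[aa_obs] + t_fact[ss - aa_obs]
                )
            else:
                logw = (gammaln(a + ra_g[idx]) + gammaln(sa_rep - a + rb_g[idx])) - (
                    t_fact[a] + t_fact[sa_rep - a]
                )
                obs = (gammaln(aa_obs + ra_g) + gammaln(ss - aa_obs + rb_g)) - (
                    t_fact[aa_obs] + t_fact[ss - aa_obs]
                )
            mask = logw <= obs[idx] + tie_eps
            # sum_a w(a) in closed form via the Vandermonde identity
            log_z = (
                (gammaln(ra_g) + gammaln(rb_g))
                + gammaln(ss + (ra_g + rb_g))
                - t_fact[ss]
                - gammaln(ra_g + rb_g)
            )
            pmf = np.exp(logw - log_z[idx])
            pvals[gsel] = np.bincount(idx, np.where(mask, pmf, 0.0), minlength=len(gsel))

    return np.minimum(pvals, 1.0)


def exact_test(
    matrix: CountMatrix,
    design: StudyDesign,
    dispersions: DispersionEstimates,
    factors: NormalizationFactors,
    pair: Sequence[str],
) -> pd.DataFrame:
    """Sum-conditioned NB exact test for one two-condition contrast.

    Pseudo-counts equalized to a common library size are summed within each
    group; the conditional enumeration of :func:`exact_nb_pvalues` yields the
    p-value.  The log2 fold change is the ratio of prior-augmented normalized
    group means (prior 0.5 per group), second condition over first.  Genes
    with zero total get p = 1 and logFC = 0.
    """
    cond_a, cond_b = pair
    groups = _group_columns(matrix, design)
    for cond in pair:
        if cond not in groups:
            raise ValueError(f"condition {cond!r} has no samples in the matrix")
    cols_a, cols_b = groups[cond_a], groups[cond_b]
    pseudo = _pseudo_counts(matrix, factors)
    s_a = pseudo[:, cols_a].sum(axis=1)
    s_b = pseudo[:, cols_b].sum(axis=1)
    n_a, n_b = len(cols_a), len(cols_b)

    phi = dispersions.per_gene(matrix.n_genes) if dispersions.mode == "tagwise" else dispersions.common
    pvalue = exact_nb_pvalues(s_a, s_b, n_a, n_b, phi)
    logfc = np.log2((s_b / n_b + LOGFC_PRIOR) / (s_a / n_a + LOGFC_PRIOR))
    zero = (s_a + s_b) == 0
    pvalue[zero] = 1.0
    logfc[zero] = 0.0
    return pd.DataFrame({"logFC": logfc, "pvalue": pvalue}, index=list(matrix.gene_ids))


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be a 1-D vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out


def run_de(
    matrix: CountMatrix,
    design: StudyDesign,
    pair: Sequence[str],
    params: AnalysisParams | None = None,
) -> DEResult:
    """Full DE pipeline for one contrast.

    TMM normalization, then dispersion estimation — common only when the
    smaller group of the pair has at most four replicates, tagwise otherwise
    (small groups make per-gene estimates unstable) — then the exact test and
    BH adjustment.  No gene filtering is applied.  All settings used are
    recorded in the result's provenance.
    """
    params = params or AnalysisParams()
    design.validate_contrast(pair)
    samples = [s for c in pair for s in design.samples(c)]
    sub = matrix.subset_samples(samples)
    sub_design = design.subset(sub.sample_ids)

    factors = tmm_factors(sub)
    n_min = min(len(sub_design.samples(c)) for c in pair)
    phi_common = estimate_common_dispersion(sub, sub_design, factors)
    if n_min <= COMMON_DISPERSION_MAX_REPLICATES:
        dispersions = DispersionEstimates(phi_common, None, "common")
    else:
        tagwise = estimate_tagwise_dispersion(
            sub, sub_design, factors, phi_common,
            prior_weight=params.dispersion_prior_weight,
        )
        dispersions = DispersionEstimates(phi_common, tagwise, "tagwise")

    et = exact_test(sub, sub_design, dispersions, factors, pair)
    padj = bh_adjust(et["pvalue"].to_numpy())
    logcpm = log_cpm(sub, factors).mean(axis=1)
    table = pd.DataFrame(
        {
            "logFC": et["logFC"].to_numpy(),
            "logCPM": logcpm,
            "pvalue": et["pvalue"].to_numpy(),
            "padj": padj,
        },
        index=list(sub.gene_ids),
    )
    provenance = {
        "pair": tuple(pair),
        "n_replicates": {c: len(sub_design.samples(c)) for c in pair},
        "dispersion_mode": dispersions.mode,
        "phi_common": float(phi_common),
        "dispersion_prior_weight": float(params.dispersion_prior_weight),
        "tmm_factors": dict(zip(factors.sample_ids, factors.factors.tolist())),
        "logfc_prior": LOGFC_PRIOR,
        "filtering": "none",
    }
    return DEResult(table, provenance)
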