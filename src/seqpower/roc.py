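"""ROC analysis over the FDR-threshold grid and the 2^-r rule.

Declaring DE at ``padj < t`` and sweeping ``t`` from 0 to 1 traces a ROC
curve against an estimated truth list.  The threshold maximizing Youden's
J = TPR - FPR is the ROC-optimal FDR threshold; fitting log2 of the optimal
threshold against the replicate number tests the empirical rule that the
optimum is approximately ``2^-r``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import AnalysisParams, CountMatrix, DEResult, StudyDesign
from .de import run_de
from .resampling import subsample_replicates
from ._seeds import derive_rng

__all__ = [
    "ROCCurve",
    "roc_curve",
    "optimal_threshold",
    "fit_threshold_vs_replicates",
    "replicate_threshold_profile",
]

#: Decade-style threshold values always included in the default grid.
DECADE_THRESHOLDS = (0.0025, 0.005, 0.01, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0)


@dataclass(frozen=True)
class ROCCurve:
    """(threshold, FPR, TPR) triples, thresholds ascending."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        fpr = np.asarray(self.fpr, dtype=float)
        tpr = np.asarray(self.tpr, dtype=float)
        if not (t.shape == fpr.shape == tpr.shape):
            raise ValueError("threshold/FPR/TPR arrays must have equal length")
        if np.any(np.diff(t) < 0):
            raise ValueError("thresholds must be ascending")
        for arr in (t, fpr, tpr):
            arr.setflags(write=False)
        object.__setattr__(self, "thresholds", t)
        object.__setattr__(self, "fpr", fpr)
        object.__setattr__(self, "tpr", tpr)

    @property
    def youden(self) -> np.ndarray:
        return self.tpr - self.fpr


def roc_curve(
    result: DEResult,
    truth: set[str],
    thresholds: Sequence[float] | None = None,
) -> ROCCurve:
    """ROC curve of a DE result against a truth list over a threshold grid.

    At each threshold ``t`` the declared set is ``{g: padj_g < t}`` (strict).
    The default grid is the sorted distinct adjusted p-values of the result,
    augmented with 0, the decade values 0.0025, 0.005, 0.01, ... 1, and a
    point just above 1 so the curve reaches (1, 1).
    """
    universe = set(result.gene_ids)
    if not truth or not truth < universe:
        raise ValueError("truth must be a non-empty strict subset of the result's genes")
    padj = result.table["padj"].to_numpy()
    in_truth = np.fromiter((g in truth for g in result.gene_ids), dtype=bool, count=len(padj))
    if thresholds is None:
        grid = np.unique(np.concatenate([padj, [0.0], DECADE_THRESHOLDS, [1.0 + 1e-9]]))
    else:
        grid = np.unique(np.asarray(thresholds, dtype=float))

    truth_sorted = np.sort(padj[in_truth])
    other_sorted = np.sort(padj[~in_truth])
    tp = np.searchsorted(truth_sorted, grid, side="left")
    fp = np.searchsorted(other_sorted, grid, side="left")
    n_truth = truth_sorted.size
    n_other = other_sorted.size
    return ROCCurve(grid, fp / n_other, tp / n_truth)


def optimal_threshold(curve: ROCCurve, criterion: str = "youden") -> float:
    """ROC-optimal threshold.

    ``youden`` maximizes J = TPR - FPR; ``corner`` minimizes the Euclidean
    distance to the perfect-classification corner (0, 1).  Ties are broken by
    the smallest threshold.
    """
    if criterion == "youden":
        score = curve.youden
    elif criterion == "corner":
        score = -np.hypot(curve.fpr, 1.0 - curve.tpr)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    best = score.max()
    idx = int(np.flatnonzero(score >= best - 1e-12)[0])
    return float(curve.thresholds[idx])


def fit_threshold_vs_replicates(
    pairs: Sequence[tuple[int, float]],
) -> tuple[float, float]:
    """OLS fit of log2(optimal threshold) on the replicate number.

    The empirical ``2^-r`` rule corresponds to slope -1 and intercept 0.
    Requires at least two distinct replicate numbers and positive thresholds.
    """
    r = np.asarray([p[0] for p in pairs], dtype=float)
    t = np.asarray([p[1] for p in pairs], dtype=float)
    if np.unique(r).size < 2:
        raise ValueError("need at least two distinct replicate numbers to fit")
    if (t <= 0).any():
        raise ValueError("thresholds must be positive to take log2")
    slope, intercept = np.polyfit(r, np.log2(t), 1)
    return float(slope), float(intercept)


def replicate_threshold_profile(
    matrix: CountMatrix,
    design: StudyDesign,
    pair: Sequence[str],
    truth: set[str],
    r_values: Sequence[int],
    n_repetitions: int = 30,
    params: AnalysisParams | None = None,
    seed: int = 0,
    criterion: str = "youden",
    return_curves: bool = False,
) -> dict[int, float] | tuple[dict[int, float], dict[int, ROCCurve]]:
    """Median ROC-optimal threshold per replicate number.

    For each ``r``, draws ``n_repetitions`` random replicate subsets (without
    replacement, independently per condition), runs the DE pipeline, computes
    the ROC curve against ``truth`` and extracts the optimal threshold; the
    per-``r`` value reported is the median over repetitions.  With
    ``return_curves`` the curve whose optimal threshold is closest to the
    median is also returned per ``r`` (a representative curve for plotting).
    """
    params = params or AnalysisParams()
    n_avail = min(len(design.samples(c)) for c in pair)
    out: dict[int, float] = {}
    curves: dict[int, ROCCurve] = {}
    for ri, r in enumerate(r_values):
        n_reps = n_repetitions if r < n_avail else 1
        thresholds: list[float] = []
        rep_curves: list[ROCCurve] = []
        for rep in range(n_reps):
            rng = derive_rng(seed, "roc", ri, rep)
            drawn, drawn_design = subsample_replicates(matrix, design, r, rng, tuple(pair))
            result = run_de(drawn, drawn_design, pair, params)
            curve = roc_curve(result, truth)
            thresholds.append(optimal_threshold(curve, criterion))
            rep_curves.append(curve)
        median = float(np.median(thresholds))
        out[int(r)] = median
        if return_curves:
            closest = int(np.argmin(np.abs(np.asarray(thresholds) - median)))
            curves[int(r)] = rep_curves[closest]
    return (out, curves) if return_curves else out
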