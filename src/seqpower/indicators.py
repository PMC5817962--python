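"""Evaluation statistics for design assessment.

Reference and truth lists, power against a stringent full-data reference,
stability (genes common to all repeated analyses), TPR/FPR/TNR against an
estimated truth list, expression strata, and the mock within-condition FPR
experiment in which every declared gene is a false positive by construction.

All threshold comparisons are strict (``padj < alpha``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisParams, CountMatrix, DEResult, StudyDesign
from .de import run_de
from ._seeds import derive_rng

__all__ = [
    "ConfusionRates",
    "reference_de_set",
    "truth_de_set",
    "power",
    "confusion_rates",
    "stability_set",
    "expression_strata",
    "genes_in_stratum",
    "mock_null_fpr",
    "replicate_specific_fraction",
]


@dataclass(frozen=True)
class ConfusionRates:
    """TPR/FPR/TNR with the counts behind them."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn)

    @property
    def tnr(self) -> float:
        return 1.0 - self.fpr

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def reference_de_set(full_result: DEResult, alpha_reference: float = 1e-4) -> set[str]:
    """Stringent full-data DE list used as the power reference."""
    return full_result.de_genes(alpha_reference)


def truth_de_set(full_result: DEResult, alpha_truth: float = 1e-3) -> set[str]:
    """Estimated-truth DE list for TPR/FPR computation."""
    return full_result.de_genes(alpha_truth)


def power(declared: set[str], reference: set[str]) -> float:
    """Fraction of the reference list recovered by the declared set."""
    if not reference:
        raise ValueError("the reference set must be non-empty")
    return len(declared & reference) / len(reference)


def confusion_rates(declared: set[str], truth: set[str], universe: set[str]) -> ConfusionRates:
    """TPR, FPR and TNR of a declared set against an estimated truth list."""
    if not truth <= universe:
        raise ValueError("truth must be a subset of the universe")
    if not declared <= universe:
        raise ValueError("declared must be a subset of the universe")
    if not (0 < len(truth) < len(universe)):
        raise ValueError("truth must be non-empty and smaller than the universe")
    tp = len(declared & truth)
    fp = len(declared - truth)
    fn = len(truth - declared)
    tn = len(universe) - tp - fp - fn
    return ConfusionRates(tp=tp, fp=fp, tn=tn, fn=fn)


def stability_set(sets: Sequence[set[str]]) -> set[str]:
    """Genes common to every repeated analysis (the stability list)."""
    if not sets:
        raise ValueError("stability_set needs at least one set")
    out = set(sets[0])
    for s in sets[1:]:
        out &= s
    return out


def replicate_specific_fraction(n_de: float, stability: float) -> float:
    """Fraction of declared DE genes that are specific to the drawn replicates.

    With a median count of declared genes ``n_de`` and a stability count (genes
    common to all repeated analyses) ``stability``, the replicate-specific
    fraction is ``1 - stability / n_de``.
    """
    if n_de <= 0:
        raise ValueError("n_de must be positive")
    if stability < 0 or stability > n_de:
        raise ValueError("stability must lie in [0, n_de]")
    return 1.0 - stability / n_de


def expression_strata(mean_logcpm: pd.Series) -> pd.Series:
    """Label genes low/medium/high by quartiles of mean logCPM.

    ``low`` below the first quartile, ``high`` above the third (strictly),
    ``medium`` otherwise.  Quartiles use linear-interpolation quantiles.
    """
    values = mean_logcpm.to_numpy(dtype=float)
    if values.size < 4:
        raise ValueError("stratification needs at least four genes")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    labels = np.where(values < q1, "low", np.where(values > q3, "high", "medium"))
    return pd.Series(labels, index=mean_logcpm.index, name="stratum")


def genes_in_stratum(strata: pd.Series, stratum: str) -> set[str]:
    return set(strata.index[strata == stratum])


def mock_null_fpr(
    condition_matrix: CountMatrix,
    group_size: int,
    n_splits: int = 30,
    alpha_fpr: float = 0.01,
    seed: int = 0,
    params: AnalysisParams | None = None,
) -> np.ndarray:
    """FPR of DE analyses between replicates of the same biological condition.

    For each split, two disjoint groups of ``group_size`` replicates are drawn
    uniformly without replacement, the full DE pipeline is run between them,
    and the FPR is the fraction of all genes with ``padj < alpha_fpr`` —
    every declaration is a false positive, since both groups come from one
    condition.  Returns the per-split FPR values.
    """
    n = condition_matrix.n_samples
    if 2 * group_size > n:
        raise ValueError(
            f"two disjoint groups of {group_size} need {2 * group_size} replicates, "
            f"only {n} available"
        )
    params = params or AnalysisParams()
    fprs = np.empty(n_splits)
    for split in range(n_splits):
        rng = derive_rng(seed, "mock_fpr", split)
        picked = rng.choice(n, size=2 * group_size, replace=False)
        group_a = [condition_matrix.sample_ids[i] for i in picked[:group_size]]
        group_b = [condition_matrix.sample_ids[i] for i in picked[group_size:]]
        design = StudyDesign(
            {**{s: "mockA" for s in group_a}, **{s: "mockB" for s in group_b}}
        )
        result = run_de(condition_matrix, design, ("mockA", "mockB"), params)
        fprs[split] = len(result.de_genes(alpha_fpr)) / condition_matrix.n_genes
    return fprs
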