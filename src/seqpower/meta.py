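"""Meta-analysis stage: contrast descriptors and pseudo-replicate surfaces.

Two operations: (1) descriptors characterizing a real pairwise contrast —
mean replicate number, mean library size, mean absolute distance between
condition means, pooled mean gene variance, and the number of DE genes — and
(2) a simulated replicate-by-depth surface of DE-gene counts built from
pseudo-replicates (multinomial draws from convex combinations of real
replicates' gene proportions).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model import AnalysisParams, CountMatrix, StudyDesign
from .de import log_cpm, run_de, tmm_factors
from .resampling import simulate_pseudo_replicates
from ._seeds import derive_rng

__all__ = ["ContrastDescriptor", "contrast_descriptors", "meta_grid", "meta_grid_summary"]


@dataclass(frozen=True)
class ContrastDescriptor:
    """Summary of one pairwise DE contrast."""

    pair: tuple[str, str]
    replicate_number: int
    mean_library_size: float
    mean_abs_distance: float
    mean_variance: float
    n_de: int | None


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def contrast_descriptors(
    matrix: CountMatrix,
    design: StudyDesign,
    pair: Sequence[str],
    alpha_de: float = 0.05,
    params: AnalysisParams | None = None,
) -> ContrastDescriptor:
    """Descriptors of a pairwise contrast, computed on normalized logCPM.

    Distance is the mean over genes of the absolute difference between
    condition means; variance is the mean over genes of the average of the
    two within-condition variances.  The replicate number is the rounded
    (half away from zero) mean of the two group sizes.  The DE count uses the
    full pipeline at ``alpha_de``; it is ``None`` when either condition has
    fewer than two replicates.
    """
    cond_a, cond_b = pair
    samples = [s for c in pair for s in design.samples(c)]
    sub = matrix.subset_samples(samples)
    factors = tmm_factors(sub)
    lcpm = log_cpm(sub, factors)
    cols = {c: [sub.sample_index(s) for s in design.samples(c) if s in sub.sample_ids] for c in pair}
    n_a, n_b = len(cols[cond_a]), len(cols[cond_b])

    mean_a = lcpm[:, cols[cond_a]].mean(axis=1)
    mean_b = lcpm[:, cols[cond_b]].mean(axis=1)
    distance = float(np.abs(mean_a - mean_b).mean())
    if min(n_a, n_b) >= 2:
        var_a = lcpm[:, cols[cond_a]].var(axis=1, ddof=1)
        var_b = lcpm[:, cols[cond_b]].var(axis=1, ddof=1)
        variance = float(((var_a + var_b) / 2.0).mean())
        n_de: int | None = len(
            run_de(sub, design.subset(sub.sample_ids), pair, params).de_genes(alpha_de)
        )
    else:
        variance = float("nan")
        n_de = None

    return ContrastDescriptor(
        pair=(cond_a, cond_b),
        replicate_number=_round_half_away((n_a + n_b) / 2.0),
        mean_library_size=float(sub.library_sizes().mean()),
        mean_abs_distance=distance,
        mean_variance=variance,
        n_de=n_de,
    )


def meta_grid(
    conditions: Mapping[str, CountMatrix],
    r_values: Sequence[int],
    library_sizes: Sequence[int],
    n_sim: int = 3,
    params: AnalysisParams | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulated DE-count surface over replicate numbers and library sizes.

    For every unordered pair of conditions, every replicate number, library
    size and repetition, ``r`` pseudo-replicates per condition are simulated
    at the given library size, the DE pipeline runs, and the number of DE
    genes at ``alpha_de`` is recorded.  The long-format table has one row per
    analysis: ``pair x |r_values| x |library_sizes| x n_sim`` rows in total.
    """
    params = params or AnalysisParams()
    labels = list(conditions)
    if len(labels) < 2:
        raise ValueError("meta_grid needs at least two conditions")
    gene_ids = None
    for label, mat in conditions.items():
        if mat.n_samples < 2:
            raise ValueError(f"condition {label!r} has fewer than two source replicates")
        if gene_ids is None:
            gene_ids = mat.gene_ids
        elif mat.gene_ids != gene_ids:
            raise ValueError(f"condition {label!r} has a different gene universe")
    if min(r_values) < 2:
        raise ValueError("replicate numbers must be >= 2")
    if min(library_sizes) <= 0:
        raise ValueError("library sizes must be positive")

    rows = []
    for pi, (la, lb) in enumerate(itertools.combinations(labels, 2)):
        for ri, r in enumerate(r_values):
            for si, size in enumerate(library_sizes):
                for rep in range(n_sim):
                    rng = derive_rng(seed, "meta", pi, ri, si, rep)
                    sim_a = simulate_pseudo_replicates(
                        conditions[la], r, size, rng, prefix=f"{la}_sim"
                    )
                    sim_b = simulate_pseudo_replicates(
                        conditions[lb], r, size, rng, prefix=f"{lb}_sim"
                    )
                    merged = CountMatrix(
                        sim_a.gene_ids,
                        sim_a.sample_ids + sim_b.sample_ids,
                        np.hstack([sim_a.counts, sim_b.counts]),
                    )
                    design = StudyDesign(
                        {**{s: la for s in sim_a.sample_ids}, **{s: lb for s in sim_b.sample_ids}}
                    )
                    result = run_de(merged, design, (la, lb), params)
                    rows.append(
                        {
                            "pair": f"{la}:{lb}",
                            "r": int(r),
                            "library_size": int(size),
                            "repetition": rep,
                            "n_de": len(result.de_genes(params.alpha_de)),
                        }
                    )
    return pd.DataFrame(rows)


def meta_grid_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Quantiles of the DE-gene count per (replicate number, library size)."""
    return (
        table.groupby(["r", "library_size"])["n_de"]
        .describe(percentiles=[0.25, 0.5, 0.75])
        .loc[:, ["min", "25%", "50%", "75%", "max"]]
        .rename(columns={"25%": "q1", "50%": "median", "75%": "q3"})
    )
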