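"""Replicate-number x library-size evaluation grid.

For every combination of replicate number ``r`` and target depth ``d``,
``n_repetitions`` data sets are built by drawing ``r`` replicates per
condition without replacement and thinning each sample to ``d`` reads; the DE
pipeline runs on each and the declared gene sets are collected.  The summary
reports, per cell, the median number of DE genes, the stability (genes common
to every repetition), the median power against a stringent full-data
reference list, and the power of the stability set — overall and restricted
to the low/high expression strata.  When ``r`` equals the number of available
replicates there is only one possible draw, so that configuration runs once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .data_model import AnalysisParams, CountMatrix, StudyDesign
from .de import run_de
from .indicators import genes_in_stratum, power
from .resampling import subsample_replicates, thin_counts
from ._seeds import derive_rng

__all__ = ["GridCell", "run_grid", "aggregate_indicators", "equal_budget_view", "budget_dominance"]


@dataclass(frozen=True)
class GridCell:
    """One subsampled DE analysis of the evaluation grid."""

    r: int
    depth: int
    repetition: int
    de_genes: frozenset[str]
    dispersion_mode: str
    seed_key: tuple = field(default=())

    @property
    def n_de(self) -> int:
        return len(self.de_genes)


def run_grid(
    matrix: CountMatrix,
    design: StudyDesign,
    params: AnalysisParams,
    pair: Sequence[str],
) -> list[GridCell]:
    """Run the full (replicate x depth x repetition) grid of DE analyses.

    Deterministic given ``params.master_seed``: every cell's generator is
    derived from (master seed, replicate index, depth index, repetition), so
    cells can be computed in any order with identical results.  Infeasible
    grid values raise before any computation starts.
    """
    design.validate_contrast(pair)
    pair_samples = [s for c in pair for s in design.samples(c)]
    sub = matrix.subset_samples(pair_samples)
    sub_design = design.subset(sub.sample_ids)
    n_avail = min(len(sub_design.samples(c)) for c in pair)
    if max(params.replicate_grid) > n_avail:
        raise ValueError(
            f"replicate grid reaches {max(params.replicate_grid)} but only "
            f"{n_avail} replicates are available per condition"
        )
    min_lib = int(sub.library_sizes().min())
    if max(params.depth_grid) > min_lib:
        raise ValueError(
            f"depth grid reaches {max(params.depth_grid)} reads but the smallest "
            f"library has {min_lib}"
        )

    cells: list[GridCell] = []
    for ri, r in enumerate(params.replicate_grid):
        n_reps = params.n_repetitions if r < n_avail else 1
        for di, depth in enumerate(params.depth_grid):
            for rep in range(n_reps):
                key = (ri, di, rep)
                rng = derive_rng(params.master_seed, "grid", *key)
                drawn, drawn_design = subsample_replicates(sub, sub_design, r, rng, pair)
                thinned = thin_counts(drawn, depth, rng)
                result = run_de(thinned, drawn_design, pair, params)
                cells.append(
                    GridCell(
                        r=r,
                        depth=depth,
                        repetition=rep,
                        de_genes=frozenset(result.de_genes(params.alpha_de)),
                        dispersion_mode=result.provenance["dispersion_mode"],
                        seed_key=key,
                    )
                )
    return cells


def _block_summary(sets: list[frozenset[str]], reference: set[str] | None) -> dict:
    counts = [len(s) for s in sets]
    stable = set(sets[0])
    for s in sets[1:]:
        stable &= s
    out = {
        "median_nde": float(np.median(counts)),
        "stability_nde": len(stable),
    }
    if reference:
        out["median_power"] = float(np.median([power(set(s), reference) for s in sets]))
        out["stability_power"] = power(stable, reference)
    else:
        out["median_power"] = np.nan
        out["stability_power"] = np.nan
    return out


def aggregate_indicators(
    cells: Sequence[GridCell],
    reference: set[str],
    strata: pd.Series | None = None,
) -> pd.DataFrame:
    """Aggregate grid cells into per-(r, depth) indicator medians and stability.

    Stratum-restricted indicators intersect both the per-repetition sets and
    the reference with the stratum's genes before computing anything.  A
    missing repetition in any block raises.
    """
    if not cells:
        raise ValueError("no grid cells to aggregate")
    if not reference:
        raise ValueError("the reference set must be non-empty")
    blocks: dict[tuple[int, int], dict[int, GridCell]] = {}
    for cell in cells:
        blocks.setdefault((cell.r, cell.depth), {})[cell.repetition] = cell
    rows = []
    for (r, depth), by_rep in sorted(blocks.items()):
        expected = set(range(len(by_rep)))
        if set(by_rep) != expected:
            missing = sorted(expected - set(by_rep))
            raise ValueError(f"cell (r={r}, depth={depth}) is missing repetitions {missing}")
        sets = [by_rep[i].de_genes for i in sorted(by_rep)]
        row: dict = {"r": r, "depth": depth}
        row.update(_block_summary(sets, reference))
        if strata is not None:
            for stratum in ("low", "high"):
                genes = genes_in_stratum(strata, stratum)
                restricted = [frozenset(s & genes) for s in sets]
                ref_restricted = reference & genes
                for key, value in _block_summary(restricted, ref_restricted).items():
                    row[f"{key}_{stratum}"] = value
        rows.append(row)
    return pd.DataFrame(rows).set_index(["r", "depth"])


def equal_budget_view(
    summary: pd.DataFrame,
    total_reads: float,
    tolerance: float = 0.15,
) -> pd.DataFrame:
    """Grid combinations whose total read budget ``r * d`` matches a target.

    Returns the qualifying rows sorted by replicate number ascending, enabling
    the replicates-versus-depth comparison at a fixed sequencing budget.
    Requires at least two qualifying combinations.
    """
    df = summary.reset_index()
    budget = df["r"] * df["depth"]
    keep = np.abs(budget - total_reads) <= tolerance * total_reads
    out = df[keep].sort_values("r", kind="mergesort").reset_index(drop=True)
    if len(out) < 2:
        raise ValueError(
            f"fewer than two grid combinations within {tolerance:.0%} of "
            f"{total_reads:g} total reads"
        )
    out["total_reads"] = out["r"] * out["depth"]
    return out


def budget_dominance(view: pd.DataFrame, indicator: str) -> str:
    """Which design axis dominates an indicator at fixed total reads.

    Spearman correlation of the indicator with the replicate number over the
    equal-budget list: positive means the indicator improves when reads are
    spent on more replicates (``replicates_dominate``); negative means depth
    wins (``depth_dominates``); zero or undefined is ``mixed``.
    """
    rho = spearmanr(view["r"], view[indicator]).statistic
    if np.isnan(rho) or rho == 0:
        return "mixed"
    return "replicates_dominate" if rho > 0 else "depth_dominates"
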