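"""Sampling devices for design evaluation.

Three operations drive the whole evaluation: drawing replicate subsets
without replacement, thinning columns to a target library size, and
simulating pseudo-replicates from convex combinations of real replicates.

Thinning works at the count level: drawing ``target`` reads without
replacement from a column is a multivariate hypergeometric draw over genes,
which matches per-read subsampling of the original library in distribution
and enforces exact column totals.
"""

from __future__ import annotations

import logging

import numpy as np

from .data_model import CountMatrix, StudyDesign
from ._seeds import derive_rng

logger = logging.getLogger(__name__)

__all__ = ["subsample_replicates", "thin_counts", "simulate_pseudo_replicates", "derive_rng"]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def subsample_replicates(
    matrix: CountMatrix,
    design: StudyDesign,
    r: int,
    seed: int | np.random.Generator,
    conditions: tuple[str, ...] | None = None,
) -> tuple[CountMatrix, StudyDesign]:
    """Draw ``r`` replicates per condition, uniformly without replacement.

    Draws are independent across conditions; counts are untouched and the
    selected samples keep the matrix's column order (canonical order).
    """
    if r < 2:
        raise ValueError("replicate number r must be >= 2")
    rng = _as_rng(seed)
    conds = conditions if conditions is not None else design.conditions
    chosen: list[str] = []
    for cond in conds:
        samples = design.samples(cond)
        if r > len(samples):
            raise ValueError(
                f"condition {cond!r} has only {len(samples)} replicates, cannot draw {r}"
            )
        picked = rng.choice(len(samples), size=r, replace=False)
        chosen.extend(samples[i] for i in picked)
    sub = matrix.subset_samples(chosen)
    return sub, design.subset(sub.sample_ids)


def thin_counts(
    matrix: CountMatrix,
    target: int,
    seed: int | np.random.Generator,
) -> CountMatrix:
    """Down-sample every column to exactly ``target`` reads.

    Per column the thinned counts are a multivariate hypergeometric draw over
    genes (reads drawn without replacement), so thinned counts never exceed
    the originals and each column sums to exactly ``target``.  Columns already
    at or below the target pass through unchanged with a logged warning.
    """
    if target < 0:
        raise ValueError("target depth must be non-negative")
    rng = _as_rng(seed)
    target = int(target)
    totals = matrix.library_sizes()
    cols = []
    for j, sample in enumerate(matrix.sample_ids):
        col = matrix.counts[:, j]
        if totals[j] <= target:
            if totals[j] < target:
                logger.warning(
                    "sample %s has %d reads, below thinning target %d; passed through",
                    sample,
                    totals[j],
                    target,
                )
            cols.append(col)
        else:
            cols.append(
                rng.multivariate_hypergeometric(col, target, method="marginals")
            )
    return matrix.with_counts(np.column_stack(cols))


def simulate_pseudo_replicates(
    condition_matrix: CountMatrix,
    n_new: int,
    target: int,
    seed: int | np.random.Generator,
    prefix: str = "sim",
) -> CountMatrix:
    """Simulate pseudo-replicates of one biological condition.

    Each new replicate draws independent uniform coefficients over the source
    replicates, normalizes them to sum to one, forms the convex combination of
    the sources' gene proportions, and draws counts from a multinomial with
    that probability vector and ``target`` total reads.  Column sums are
    exactly ``target``.
    """
    if n_new < 1:
        raise ValueError("n_new must be >= 1")
    if target < 0:
        raise ValueError("target depth must be non-negative")
    rng = _as_rng(seed)
    totals = condition_matrix.library_sizes()
    if (totals == 0).any():
        bad = condition_matrix.sample_ids[int(np.argmax(totals == 0))]
        raise ValueError(f"source replicate {bad!r} has zero total count")
    props = condition_matrix.counts / totals  # genes x sources
    k = condition_matrix.n_samples
    cols = []
    for _ in range(n_new):
        w = rng.uniform(size=k)
        w = w / w.sum()
        p = props @ w
        p = p / p.sum()  # guard floating-point drift away from 1
        cols.append(rng.multinomial(int(target), p))
    sample_ids = tuple(f"{prefix}_{i + 1}" for i in range(n_new))
    return CountMatrix(condition_matrix.gene_ids, sample_ids, np.column_stack(cols))
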