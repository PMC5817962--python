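"""Synthetic two-condition pilot data with known truth.

The generator emulates a bulk RNA-seq pilot of the kind used for
experimental-design evaluation: two biological conditions, up to eight (or
more) biological replicates each, library sizes in the millions of reads, a
large fraction of truly DE genes with heterogeneous fold changes, and
gene-wise negative-binomial dispersions.

Model
-----
Relative gene abundances ``q_g`` are log-normal.  A gene is DE with
probability ``pi_de``; its true log2 fold change has a random sign (balanced
up/down) and a zero-truncated normal magnitude (``|lfc| >= lfc_min``).  The
effect is split symmetrically between conditions (condition A is scaled by
``2^(-lfc/2)``, condition B by ``2^(+lfc/2)``), so the grand-mean abundance is
effect-free and composition bias stays small.  Counts for sample ``j`` of
condition ``c`` are negative binomial with mean ``L_j * q_g * 2^(s_c lfc_g/2)
/ normalizer_c`` (the normalizer makes expected column sums hit the target
library size) and variance ``mu (1 + mu phi_g)``, with gene-wise dispersions
``phi_g ~ Gamma(shape, scale)``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .data_model import CountMatrix, StudyDesign, SyntheticTruth
from ._seeds import derive_rng

__all__ = ["PilotSpec", "generate_pilot", "generate_null_condition", "empirical_lfc_check"]


@dataclass(frozen=True)
class PilotSpec:
    """Parameters of a synthetic two-condition pilot experiment.

    Defaults describe a tomato-fruit-development-like bulk design: 20,000
    genes, eight replicates per condition, 5 M reads per sample, about half
    the genes truly DE, and gamma gene-wise dispersions with mean 0.05
    (shape 2, scale 0.025), typical of plant bulk RNA-seq.
    """

    n_genes: int = 20_000
    replicates_per_condition: int = 8
    target_library_size: int = 5_000_000
    pi_de: float = 0.5
    lfc_sd: float = 1.0
    lfc_min: float = 0.25
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 2.0
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.025
    constant_dispersion: float | None = None
    condition_labels: tuple[str, str] = ("A", "B")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if not (0.0 <= self.pi_de <= 1.0):
            raise ValueError("pi_de must lie in [0, 1]")
        for name in (
            "target_library_size",
            "lfc_sd",
            "baseline_log_sd",
            "dispersion_shape",
            "dispersion_scale",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be >= 0")
        if self.replicates_per_condition < 2:
            raise ValueError("at least two replicates per condition are required")
        if self.constant_dispersion is not None and self.constant_dispersion < 0:
            raise ValueError("constant_dispersion must be >= 0")

    def evolve(self, **kwargs) -> "PilotSpec":
        return replace(self, **kwargs)


def _draw_truth(spec: PilotSpec, rng: np.random.Generator) -> np.ndarray:
    """True per-gene log2 fold changes (0 for non-DE genes)."""
    lfc = np.zeros(spec.n_genes)
    de = rng.random(spec.n_genes) < spec.pi_de
    n_de = int(de.sum())
    if n_de == 0:
        return lfc
    a = spec.lfc_min / spec.lfc_sd  # truncation point in standard units
    mag = stats.truncnorm.rvs(a, np.inf, loc=0.0, scale=spec.lfc_sd, size=n_de, random_state=rng)
    mag = np.maximum(mag, np.nextafter(spec.lfc_min, np.inf) if spec.lfc_min > 0 else mag)
    signs = np.ones(n_de)
    signs[: n_de // 2] = -1.0  # balanced up/down split
    rng.shuffle(signs)
    lfc[de] = signs * mag
    return lfc


def _nb_column(rng: np.random.Generator, mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mu, phi) draws via gamma-Poisson mixing; Poisson where phi ~ 0."""
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = phi < 1e-12
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        shape = 1.0 / phi[~tiny]
        lam = rng.gamma(shape, mu[~tiny] / shape)
        out[~tiny] = rng.poisson(lam)
    return out


def generate_pilot(spec: PilotSpec) -> tuple[CountMatrix, StudyDesign, SyntheticTruth]:
    """Generate a two-condition pilot count matrix with known truth.

    Fully reproducible from ``spec.seed``; the truth flags exactly the genes
    with nonzero true log2 fold change.
    """
    rng = derive_rng(spec.seed, "pilot")
    G = spec.n_genes
    q = rng.lognormal(spec.baseline_log_mean, spec.baseline_log_sd, G)
    lfc = _draw_truth(spec, rng)
    if spec.constant_dispersion is not None:
        phi = np.full(G, float(spec.constant_dispersion))
    else:
        phi = rng.gamma(spec.dispersion_shape, spec.dispersion_scale, G)

    gene_ids = tuple(f"g{i:06d}" for i in range(G))
    labels = spec.condition_labels
    sample_ids: list[str] = []
    assignments: dict[str, str] = {}
    cols: list[np.ndarray] = []
    for cond, sign in zip(labels, (-1.0, +1.0)):
        abundance = q * np.exp2(sign * lfc / 2.0)
        p = abundance / abundance.sum()
        mu = spec.target_library_size * p
        for i in range(spec.replicates_per_condition):
            sid = f"{cond}_{i + 1}"
            sample_ids.append(sid)
            assignments[sid] = cond
            cols.append(_nb_column(rng, mu, phi))

    matrix = CountMatrix(gene_ids, tuple(sample_ids), np.column_stack(cols))
    truth = SyntheticTruth(gene_ids, lfc != 0.0, lfc)
    return matrix, StudyDesign(assignments), truth


def generate_null_condition(
    n_genes: int = 20_000,
    n_replicates: int = 12,
    target_library_size: int = 5_000_000,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[CountMatrix, StudyDesign]:
    """One biological condition with no DE structure (for mock comparisons).

    Built as a pilot with ``pi_de = 0``, keeping only the first condition's
    columns, so its abundance/dispersion profile matches :func:`generate_pilot`.
    """
    spec = PilotSpec(
        n_genes=n_genes,
        replicates_per_condition=n_replicates,
        target_library_size=target_library_size,
        pi_de=0.0,
        seed=seed,
        **spec_kwargs,
    )
    matrix, design, _ = generate_pilot(spec)
    cond = spec.condition_labels[0]
    samples = design.samples(cond)
    return matrix.subset_samples(samples), design.subset(samples)


def empirical_lfc_check(
    matrix: CountMatrix,
    design: StudyDesign,
    truth: SyntheticTruth,
    prior_cpm: float = 0.5,
) -> float:
    """Mean absolute error of the naive log2 fold change on true DE genes.

    A calibration harness for the generator: library-size-normalized mean CPM
    is computed per condition, and the observed ``log2`` ratio (with a small
    prior to guard zeros) is compared with the true lfc.  Requires at least
    four replicates per condition and a non-empty truth set.
    """
    if tuple(truth.gene_ids) != tuple(matrix.gene_ids):
        raise ValueError("truth and matrix gene ids differ")
    conds = design.conditions
    if len(conds) != 2:
        raise ValueError("exactly two conditions are required")
    for c in conds:
        if len(design.samples(c)) < 4:
            raise ValueError(f"condition {c!r} needs >= 4 replicates for this check")
    de = truth.is_de
    if not de.any():
        raise ValueError("no DE genes in the truth set")

    cpm = matrix.counts / matrix.library_sizes() * 1e6
    means = {}
    for c in conds:
        idx = [matrix.sample_index(s) for s in design.samples(c)]
        means[c] = cpm[:, idx].mean(axis=1)
    a, b = conds
    observed = np.log2((means[b] + prior_cpm) / (means[a] + prior_cpm))
    return float(np.abs(observed[de] - truth.lfc[de]).mean())
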