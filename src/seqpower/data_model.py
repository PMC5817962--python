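"""Core data types, file I/O and run configuration.

The whole package works on three small objects: a :class:`CountMatrix`
(gene-by-sample integer read counts), a :class:`StudyDesign` (sample to
biological-condition assignment) and :class:`AnalysisParams` (the thresholds
and grids of an evaluation run).  Differential-expression output is carried by
:class:`DEResult`, and synthetic data come with a :class:`SyntheticTruth`.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "StudyDesign",
    "AnalysisParams",
    "DEResult",
    "SyntheticTruth",
    "read_count_table",
    "write_count_table",
    "write_gene_set",
    "read_gene_set",
    "write_indicator_table",
]


@dataclass(frozen=True)
class CountMatrix:
    """Gene-by-sample matrix of non-negative integer read counts.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene identifiers (rows).
    sample_ids
        Ordered, unique sample identifiers (columns).
    counts
        Integer array of shape ``(len(gene_ids), len(sample_ids))``.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(counts, 1), 0)):
                raise ValueError("counts must be integral")
            counts = counts.astype(np.int64)
        else:
            counts = counts.astype(np.int64, copy=False)
        if counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if counts.size and counts.min() < 0:
            g, s = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample total read counts (column sums)."""
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        """Restrict to the given samples, keeping this matrix's column order."""
        wanted = set(sample_ids)
        unknown = wanted - set(self.sample_ids)
        if unknown:
            raise KeyError(f"unknown samples: {sorted(unknown)}")
        keep = [j for j, s in enumerate(self.sample_ids) if s in wanted]
        return CountMatrix(
            self.gene_ids,
            tuple(self.sample_ids[j] for j in keep),
            self.counts[:, keep],
        )

    def with_counts(self, counts: np.ndarray) -> "CountMatrix":
        return CountMatrix(self.gene_ids, self.sample_ids, counts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountMatrix":
        return cls(tuple(map(str, df.index)), tuple(map(str, df.columns)), df.to_numpy())


@dataclass(frozen=True)
class StudyDesign:
    """Mapping of each sample to exactly one biological condition."""

    assignments: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "assignments", dict((str(k), str(v)) for k, v in self.assignments.items())
        )

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.assignments.values():
            seen.setdefault(c, None)
        return tuple(seen)

    def samples(self, condition: str) -> tuple[str, ...]:
        out = tuple(s for s, c in self.assignments.items() if c == condition)
        if not out:
            raise KeyError(f"no samples assigned to condition {condition!r}")
        return out

    def replicate_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.assignments.values():
            counts[c] = counts.get(c, 0) + 1
        return counts

    def subset(self, sample_ids: Iterable[str]) -> "StudyDesign":
        keep = set(sample_ids)
        return StudyDesign({s: c for s, c in self.assignments.items() if s in keep})

    def validate_contrast(self, pair: Sequence[str], min_reps: int = 2) -> None:
        """Check that both conditions of a DE contrast have enough replicates."""
        if len(pair) != 2 or pair[0] == pair[1]:
            raise ValueError(f"a contrast needs two distinct conditions, got {pair!r}")
        for cond in pair:
            n = len(self.samples(cond))
            if n < min_reps:
                raise ValueError(
                    f"condition {cond!r} has {n} replicate(s); at least {min_reps} required"
                )

    def to_tsv(self, path: str | os.PathLike) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("sample\tcondition\n")
            for s, c in self.assignments.items():
                fh.write(f"{s}\t{c}\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "StudyDesign":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if list(df.columns[:2]) != ["sample", "condition"]:
            raise ValueError("design file must have header 'sample<TAB>condition'")
        if df["sample"].duplicated().any():
            dup = df["sample"][df["sample"].duplicated()].iloc[0]
            raise ValueError(f"sample {dup!r} assigned more than once")
        return cls(dict(zip(df["sample"], df["condition"])))


#: Default replicate-number grid evaluated by the design stage.
DEFAULT_REPLICATE_GRID = (2, 3, 4, 5, 6, 7)
#: Default library-size (read-depth) grid, in reads per sample.
DEFAULT_DEPTH_GRID = (2_500_000, 5_000_000, 7_500_000, 10_000_000, 15_000_000, 20_000_000)


@dataclass(frozen=True)
class AnalysisParams:
    """Thresholds, grids and seeds of one evaluation run.

    ``alpha_de`` declares DE in routine analyses; ``alpha_reference`` builds the
    stringent full-data reference list used for power; ``alpha_truth`` builds
    the estimated-truth list for TPR/FPR; ``alpha_fpr`` is the threshold used
    in FPR experiments.  All comparisons against these thresholds are strict
    (``padj < alpha``).
    """

    alpha_de: float = 0.05
    alpha_reference: float = 1e-4
    alpha_truth: float = 1e-3
    alpha_fpr: float = 0.01
    n_repetitions: int = 45
    n_fpr_repetitions: int = 30
    replicate_grid: tuple[int, ...] = DEFAULT_REPLICATE_GRID
    depth_grid: tuple[int, ...] = DEFAULT_DEPTH_GRID
    dispersion_prior_weight: float = 10.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_de", "alpha_reference", "alpha_truth", "alpha_fpr"):
            a = getattr(self, name)
            if not (0.0 < a <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {a}")
        if self.n_repetitions < 1 or self.n_fpr_repetitions < 1:
            raise ValueError("repetition counts must be >= 1")
        object.__setattr__(self, "replicate_grid", tuple(int(r) for r in self.replicate_grid))
        object.__setattr__(self, "depth_grid", tuple(int(d) for d in self.depth_grid))
        if not self.replicate_grid or not self.depth_grid:
            raise ValueError("replicate_grid and depth_grid must be non-empty")
        if min(self.replicate_grid) < 2:
            raise ValueError("replicate numbers must be >= 2")
        if min(self.depth_grid) <= 0:
            raise ValueError("depths must be positive")
        if self.dispersion_prior_weight < 0:
            raise ValueError("dispersion_prior_weight must be >= 0")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "AnalysisParams":
        """Load parameters from a flat key-value (YAML) document.

        Unknown keys raise, so typos in threshold names cannot pass silently.
        """
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError("config must be a flat key-value document")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("replicate_grid", "depth_grid"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = tuple(float(x) for x in raw[key].split(","))
        return cls(**raw)

    def evolve(self, **kwargs) -> "AnalysisParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class DEResult:
    """Per-gene output of one differential-expression contrast.

    ``table`` is indexed by gene id with columns ``logFC`` (log2 fold change of
    the second condition of the pair over the first), ``logCPM`` (mean log2
    counts-per-million), ``pvalue`` and ``padj`` (Benjamini-Hochberg).
    ``provenance`` records the settings the pipeline actually used.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"logFC", "logCPM", "pvalue", "padj"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"DEResult table missing columns {sorted(missing)}")
        p = self.table["pvalue"].to_numpy()
        q = self.table["padj"].to_numpy()
        if ((p < 0) | (p > 1)).any() or ((q < 0) | (q > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        if (q < p - 1e-12).any():
            raise ValueError("adjusted p-values must not be smaller than raw p-values")
        if self.table.index.duplicated().any():
            raise ValueError("duplicate gene ids in DE result")

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.table.index)

    def de_genes(self, alpha: float) -> set[str]:
        """Genes declared DE at ``padj < alpha`` (strict)."""
        return set(self.table.index[self.table["padj"].to_numpy() < alpha])

    def to_tsv(self, path: str | os.PathLike) -> None:
        out = self.table.copy()
        out.insert(0, "gene", out.index)
        out.to_csv(path, sep="\t", index=False, lineterminator="\n")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a synthetic pilot: DE flag and true log2 fold change."""

    gene_ids: tuple[str, ...]
    is_de: np.ndarray
    lfc: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        is_de = np.asarray(self.is_de, dtype=bool)
        lfc = np.asarray(self.lfc, dtype=float)
        if is_de.shape != (len(self.gene_ids),) or lfc.shape != is_de.shape:
            raise ValueError("truth arrays must match gene_ids length")
        if np.any(~is_de & (lfc != 0.0)) or np.any(is_de & (lfc == 0.0)):
            raise ValueError("is_de must be true exactly where the true lfc is nonzero")
        is_de.setflags(write=False)
        lfc.setflags(write=False)
        object.__setattr__(self, "is_de", is_de)
        object.__setattr__(self, "lfc", lfc)

    def de_genes(self) -> set[str]:
        return {g for g, f in zip(self.gene_ids, self.is_de) if f}

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = pd.DataFrame(
            {"gene": self.gene_ids, "is_de": self.is_de.astype(int), "lfc": self.lfc}
        )
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "SyntheticTruth":
        df = pd.read_csv(path, sep="\t", dtype={"gene": str})
        return cls(tuple(df["gene"]), df["is_de"].to_numpy(bool), df["lfc"].to_numpy(float))


def _parse_int_cell(text: str, gene: str, sample: str) -> int:
    """Strict integer parser: no thousands separators, no floats, no blanks."""
    t = text.strip()
    if not t or not t.lstrip("-").isdigit():
        raise ValueError(f"non-integer count {text!r} at gene {gene!r}, sample {sample!r}")
    value = int(t)
    if value < 0:
        raise ValueError(f"negative count {value} at gene {gene!r}, sample {sample!r}")
    return value


def _read_matrix_tsv(path: str | os.PathLike) -> CountMatrix:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must contain gene column plus sample ids")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}: row {parts[0]!r} has {len(parts) - 1} values, "
                    f"expected {len(sample_ids)}"
                )
            gene_ids.append(parts[0])
            rows.append(
                [_parse_int_cell(v, parts[0], s) for v, s in zip(parts[1:], sample_ids)]
            )
    counts = np.asarray(rows, dtype=np.int64).reshape(len(gene_ids), len(sample_ids))
    return CountMatrix(tuple(gene_ids), tuple(sample_ids), counts)


def _read_htseq_pair(paths: Sequence[str | os.PathLike]) -> CountMatrix:
    """Merge per-sample two-column HTSeq-count files on gene id.

    Summary rows whose gene id starts with ``__`` (e.g. ``__no_feature``) are
    dropped; the number dropped per file is logged.  Sample ids come from the
    file stems; genes are returned in lexicographic order.
    """
    if not paths:
        raise ValueError("htseq_pair dialect requires at least one file")
    per_sample: dict[str, dict[str, int]] = {}
    for p in paths:
        sample = Path(p).stem
        table: dict[str, int] = {}
        dropped = 0
        with open(p, "r", encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{p}: expected two tab-separated columns")
                gene, value = parts
                if gene.startswith("__"):
                    dropped += 1
                    continue
                if gene in table:
                    raise ValueError(f"{p}: duplicate gene {gene!r}")
                table[gene] = _parse_int_cell(value, gene, sample)
        logger.info("dropped %d HTSeq summary row(s) from %s", dropped, p)
        per_sample[sample] = table

    gene_sets = {s: set(t) for s, t in per_sample.items()}
    samples = list(per_sample)
    ref_genes = gene_sets[samples[0]]
    for s in samples[1:]:
        if gene_sets[s] != ref_genes:
            divergent = sorted(gene_sets[s] ^ ref_genes)[0]
            raise ValueError(
                f"gene sets differ across HTSeq files: {divergent!r} is not shared "
                f"between {samples[0]!r} and {s!r}"
            )
    gene_ids = tuple(sorted(ref_genes))
    counts = np.asarray(
        [[per_sample[s][g] for s in samples] for g in gene_ids], dtype=np.int64
    ).reshape(len(gene_ids), len(samples))
    return CountMatrix(gene_ids, tuple(samples), counts)


def read_count_table(
    path: str | os.PathLike | Sequence[str | os.PathLike],
    dialect: str = "matrix_tsv",
) -> CountMatrix:
    """Read raw counts from disk.

    ``matrix_tsv``: a single TSV with header ``gene<TAB>sample1...`` and one
    row per gene.  ``htseq_pair``: a list of two-column ``(gene, count)`` files
    (or a directory of them), one per sample, merged on gene id.
    """
    if dialect == "matrix_tsv":
        if isinstance(path, (list, tuple)):
            raise ValueError("matrix_tsv dialect takes a single file path")
        return _read_matrix_tsv(path)
    if dialect == "htseq_pair":
        if isinstance(path, (str, os.PathLike)) and Path(path).is_dir():
            paths: Sequence = sorted(Path(path).iterdir())
        elif isinstance(path, (list, tuple)):
            paths = path
        else:
            paths = [path]
        return _read_htseq_pair(paths)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_count_table(matrix: CountMatrix, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for g, row in zip(matrix.gene_ids, matrix.counts):
            fh.write(g + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_gene_set(genes: Iterable[str], path: str | os.PathLike) -> None:
    """Write a gene set as one id per line, LF endings, lexicographic order."""
    ids = sorted(str(g) for g in genes)
    if any(not g for g in ids):
        raise ValueError("gene ids must be non-empty strings")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in ids:
            fh.write(g + "\n")


def read_gene_set(path: str | os.PathLike) -> set[str]:
    with open(path, "r", encoding="utf-8") as fh:
        return {line.rstrip("\n") for line in fh if line.strip()}


def write_indicator_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write an indicator summary TSV, rows ordered by r then depth."""
    df = table.reset_index() if table.index.nlevels > 1 else table.copy()
    for col in ("r", "depth"):
        if col not in df.columns:
            raise ValueError(f"indicator table must carry a {col!r} column")
    df = df.sort_values(["r", "depth"], kind="mergesort")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
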