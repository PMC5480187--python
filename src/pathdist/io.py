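"""Readers, writers and containers for expression matrices, gene sets
(GMT), distance/score matrices and cluster-label tables.

All text formats are tab-separated, UTF-8, '.' decimal, no thousands
separators, so that written output is bit-comparable across runs.
Gene-identifier matching is exact and case-sensitive throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DataError,
    DuplicateIdentifierError,
    MatrixParseError,
    ParameterError,
    ShapeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "GeneSetCollection",
    "DistanceMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gmt",
    "write_gmt",
    "read_distance_matrix",
    "write_distance_matrix",
    "read_labels",
    "write_labels",
    "match_pathways",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise DuplicateIdentifierError(f"duplicated {what} {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A gene-by-sample matrix of continuous (log-scale) expression values.

    ``values[i, j]`` is the expression of gene ``gene_ids[i]`` in sample
    ``sample_ids[j]``.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.gene_ids),
            len(self.sample_ids),
        ):
            raise ShapeError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(self.gene_ids) < 1 or len(self.sample_ids) < 2:
            raise ShapeError("need at least 1 gene and 2 samples")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def submatrix(self, genes: list[str]) -> np.ndarray:
        """Samples-by-genes slice for the given genes (in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            rows = [index[g] for g in genes]
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in expression matrix") from exc
        return self.values[rows, :].T


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways); insertion order is preserved."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) < 1:
                raise ShapeError(f"gene set {name!r} is empty")
            _check_unique(genes, f"gene in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {name: len(genes) for name, genes in self.sets.items()}

    def all_genes(self) -> list[str]:
        """Union of member genes, first-occurrence order, de-duplicated."""
        seen: dict[str, None] = {}
        for genes in self.sets.values():
            for g in genes:
                seen.setdefault(g)
        return list(seen)


@dataclass
class DistanceMatrix:
    """A symmetric nonnegative pairwise distance with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ShapeError(f"distance matrix shape {self.values.shape} != ({n}, {n})")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            raise DataError("distance matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise DataError("distance matrix contains negative entries")
        if not np.allclose(self.values, self.values.T):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise DataError("distance matrix diagonal is not zero")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path: str | Path) -> ExpressionMatrix:
    """Read a tab-separated gene-by-sample matrix.

    The first row is a header: a gene-identifier column name followed by the
    sample identifiers.  Each subsequent row is a gene id followed by one
    numeric value per sample.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MatrixParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ShapeError(f"{path}: fewer than 2 samples")
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    _check_unique(gene_ids, "gene id")
    _check_unique(sample_ids, "sample id")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            # astype(float) round-trips "%.17g" output exactly, unlike the
            # fast to_numeric parser
            values[:, j] = df[col].astype(float)
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise MatrixParseError(
                f"{path}: non-numeric or missing value at gene {bad!r}, sample {col!r}"
            ) from None
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise MatrixParseError(
            f"{path}: missing value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression_matrix(
    expr: ExpressionMatrix, path: str | Path, id_column: str = "gene_id"
) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = id_column
    df.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, then member genes).

    Duplicate genes within one line are dropped (first occurrence kept) with
    a warning; a duplicate set name is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MatrixParseError(
                    f"{path}:{lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise DuplicateIdentifierError(
                    f"{path}:{lineno}: duplicate gene-set name {name!r}"
                )
            genes: list[str] = []
            seen: set[str] = set()
            dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                genes.append(g)
            if dups:
                logger.warning(
                    "%s:%d: set %r: %d duplicate gene id(s) dropped",
                    path,
                    lineno,
                    name,
                    dups,
                )
            sets[name] = genes
    return GeneSetCollection(sets)


def write_gmt(
    sets: GeneSetCollection, path: str | Path, description: str = "na"
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# distance matrices and labels


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square tab-separated matrix with sample ids as header and
    first column."""
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, float_precision="round_trip")
    sample_ids = [str(s) for s in df.columns]
    row_ids = [str(s) for s in df.index]
    if sample_ids != row_ids:
        raise MatrixParseError(f"{path}: row and column sample ids differ")
    return DistanceMatrix(sample_ids, df.to_numpy(dtype=float))


def write_distance_matrix(dist: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dist.values, index=dist.sample_ids, columns=dist.sample_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read a two-column (sample_id, integer label) tab-separated table."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] != 2:
        raise MatrixParseError(f"{path}: expected exactly 2 columns")
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    _check_unique(sample_ids, "sample id")
    try:
        labels = df.iloc[:, 1].astype(int).to_numpy()
    except (ValueError, TypeError) as exc:
        raise MatrixParseError(f"{path}: non-integer label: {exc}") from None
    return sample_ids, labels


def write_labels(
    sample_ids: list[str], labels: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame({"sample_id": sample_ids, "label": np.asarray(labels, int)}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# pathway matching


def match_pathways(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    min_size: int = 2,
) -> tuple[GeneSetCollection, pd.DataFrame]:
    """Intersect each pathway with the measured genes and drop small ones.

    Matching is exact and case-sensitive.  Pathways whose intersection with
    ``expr.gene_ids`` has fewer than ``min_size`` genes are dropped.  Returns
    the filtered collection and a per-pathway coverage table with columns
    ``pathway``, ``n_annotated``, ``n_matched``, ``kept``.

    The default ``min_size=2`` is the smallest size at which a multivariate
    mixture is non-degenerate.
    """
    if min_size < 2:
        raise ParameterError(f"min_size must be >= 2, got {min_size}")
    measured = set(expr.gene_ids)
    kept: dict[str, list[str]] = {}
    rows = []
    for name, genes in sets:
        matched = [g for g in genes if g in measured]
        keep = len(matched) >= min_size
        if keep:
            kept[name] = matched
        rows.append(
            {
                "pathway": name,
                "n_annotated": len(genes),
                "n_matched": len(matched),
                "kept": keep,
            }
        )
    coverage = pd.DataFrame(rows, columns=["pathway", "n_annotated", "n_matched", "kept"])
    if not kept:
        raise ConfigurationError(
            "no pathway retained at least "
            f"{min_size} measured genes; check that the gene-identifier "
            "namespaces of the expression matrix and the gene sets agree"
        )
    return GeneSetCollection(kept), coverage
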