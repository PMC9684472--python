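"""Input/output and expression preprocessing.

Expression matrices are stored genes x locations. Raw counts are filtered,
log-normalized (per-location totals scaled to a fixed constant, then log1p)
and finally standardized per gene to zero mean and unit sample standard
deviation, which is the scale the factor model expects.

Supported on-disk formats are Matrix Market triplets with companion gene and
barcode text files, dense TSV/CSV with a header row of location ids, and
coordinate tables with columns ``id,x,y[,z]``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "ExpressionMatrix",
    "CovariateTable",
    "filter_matrix",
    "normalize_and_standardize",
    "select_genes",
    "read_mtx",
    "write_mtx",
    "read_dense",
    "write_dense",
    "read_coordinates",
    "write_coordinates",
]

#: per-location total to which counts are scaled before log1p
NORMALIZATION_TARGET = 10_000.0

State = Literal["counts", "normalized", "standardized"]


@dataclass
class ExpressionMatrix:
    """Gene x location expression values with identifiers and a state flag."""

    values: np.ndarray
    gene_ids: list[str]
    location_ids: list[str]
    state: State = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        m, n = self.values.shape
        if len(self.gene_ids) != m:
            raise ValueError(f"{len(self.gene_ids)} gene ids for {m} rows")
        if len(self.location_ids) != n:
            raise ValueError(f"{len(self.location_ids)} location ids for {n} columns")
        if len(set(self.gene_ids)) != m:
            raise ValueError("duplicate gene ids")
        if len(set(self.location_ids)) != n:
            raise ValueError("duplicate location ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression matrix contains non-finite values")
        if self.state == "counts":
            if np.any(self.values < 0) or np.any(self.values != np.round(self.values)):
                raise ValueError("counts state requires non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_locations(self) -> int:
        return self.values.shape[1]


@dataclass
class CovariateTable:
    """Location x q covariate matrix whose first column is an intercept."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first covariate column must be an intercept of ones")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("covariate matrix is rank deficient")

    @property
    def q(self) -> int:
        return self.values.shape[1]

    @classmethod
    def intercept_only(cls, n_locations: int) -> "CovariateTable":
        return cls(np.ones((n_locations, 1)))


def filter_matrix(
    expr: ExpressionMatrix,
    min_locations_per_gene: int = 20,
    min_genes_per_location: int = 20,
) -> ExpressionMatrix:
    """Drop lowly detected genes, then sparsely covered locations.

    A gene survives when it has non-zero counts in at least
    ``min_locations_per_gene`` locations; a location survives when (after the
    gene filter) it has non-zero counts for at least ``min_genes_per_location``
    genes. Each filter is applied in a single pass, genes first.
    """
    if expr.state != "counts":
        raise ValueError("filtering operates on raw counts")
    nonzero = expr.values > 0
    gene_keep = nonzero.sum(axis=1) >= min_locations_per_gene
    if not gene_keep.any():
        raise ValueError(
            f"no gene is detected in >= {min_locations_per_gene} locations"
        )
    values = expr.values[gene_keep]
    loc_keep = (values > 0).sum(axis=0) >= min_genes_per_location
    if not loc_keep.any():
        raise ValueError(
            f"no location has >= {min_genes_per_location} detected genes"
        )
    return ExpressionMatrix(
        values=values[:, loc_keep],
        gene_ids=[g for g, k in zip(expr.gene_ids, gene_keep) if k],
        location_ids=[s for s, k in zip(expr.location_ids, loc_keep) if k],
        state="counts",
    )


def normalize_and_standardize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Log-normalize counts and z-score each gene.

    Counts are scaled so every location sums to ``NORMALIZATION_TARGET`` and
    log1p-transformed; pre-normalized input skips that step. Every gene row is
    then centered and scaled to unit sample standard deviation. Zero-variance
    genes are dropped with a warning, as are zero-count locations.
    """
    if expr.state == "standardized":
        return expr
    values = expr.values
    location_ids = list(expr.location_ids)
    if expr.state == "counts":
        totals = values.sum(axis=0)
        empty = totals == 0
        if empty.any():
            warnings.warn(
                f"dropping {int(empty.sum())} zero-count location(s)", stacklevel=2
            )
            values = values[:, ~empty]
            totals = totals[~empty]
            location_ids = [s for s, e in zip(location_ids, empty) if not e]
        values = np.log1p(values / totals * NORMALIZATION_TARGET)
    gene_ids = list(expr.gene_ids)
    sd = values.std(axis=1, ddof=1)
    degenerate = sd <= 0
    if degenerate.any():
        warnings.warn(
            f"dropping {int(degenerate.sum())} zero-variance gene(s)", stacklevel=2
        )
        values = values[~degenerate]
        sd = sd[~degenerate]
        gene_ids = [g for g, d in zip(gene_ids, degenerate) if not d]
    values = (values - values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(values, gene_ids, location_ids, state="standardized")


def select_genes(
    expr: ExpressionMatrix,
    mode: Literal["list", "hvg"] = "hvg",
    k: int | None = None,
    gene_list: Sequence[str] | None = None,
) -> ExpressionMatrix:
    """Subset to a named gene list or the top-k most variable genes."""
    if mode == "list":
        if gene_list is None:
            raise ValueError("mode='list' requires gene_list")
        index = {g: i for i, g in enumerate(expr.gene_ids)}
        missing = [g for g in gene_list if g not in index]
        if missing:
            raise KeyError(f"genes not present: {missing}")
        rows = [index[g] for g in gene_list]
    elif mode == "hvg":
        if k is None:
            raise ValueError("mode='hvg' requires k")
        if k > expr.n_genes:
            raise ValueError(f"k={k} exceeds the {expr.n_genes} available genes")
        variances = expr.values.var(axis=1, ddof=1)
        # stable sort keeps the input order among exact variance ties
        order = np.argsort(-variances, kind="stable")
        rows = sorted(order[:k].tolist())
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return replace(
        expr,
        values=expr.values[rows],
        gene_ids=[expr.gene_ids[i] for i in rows],
    )


# ---------------------------------------------------------------------------
# on-disk formats


def read_mtx(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    state: State = "counts",
) -> ExpressionMatrix:
    """Read a Matrix Market triplet file with gene/barcode companions."""
    mat = spio.mmread(str(matrix_path))
    if sparse.issparse(mat):
        mat = mat.toarray()
    genes = Path(genes_path).read_text().split()
    barcodes = Path(barcodes_path).read_text().split()
    return ExpressionMatrix(np.asarray(mat, float), genes, barcodes, state=state)


def write_mtx(
    expr: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
) -> None:
    mat = sparse.coo_matrix(expr.values)
    spio.mmwrite(str(matrix_path), mat, precision=17)
    Path(genes_path).write_text("\n".join(expr.gene_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(expr.location_ids) + "\n")


def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_dense(path: str | Path, state: State = "counts") -> ExpressionMatrix:
    """Read a dense gene x location table; header row holds location ids."""
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return ExpressionMatrix(
        df.to_numpy(float),
        [str(g) for g in df.index],
        [str(s) for s in df.columns],
        state=state,
    )


def write_dense(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.location_ids)
    df.to_csv(path, sep=_sep_for(path), float_format="%.17g")


def read_coordinates(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read an ``id,x,y[,z]`` table; row order defines the location index."""
    df = pd.read_csv(path, sep=_sep_for(path))
    axis_cols = [c for c in ("x", "y", "z") if c in df.columns]
    if "id" not in df.columns or len(axis_cols) < 2:
        raise ValueError("coordinate table must have columns id,x,y[,z]")
    return df[axis_cols].to_numpy(float), [str(i) for i in df["id"]]


def write_coordinates(
    coords: np.ndarray, ids: Sequence[str], path: str | Path
) -> None:
    cols = ["x", "y", "z"][: coords.shape[1]]
    df = pd.DataFrame(coords, columns=cols)
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep=_sep_for(path), index=False, float_format="%.17g")
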