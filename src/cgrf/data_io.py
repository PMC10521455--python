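"""Expression-matrix I/O and preprocessing.

The universal currency of the pipeline is a genes x timepoints matrix with
unique gene identifiers and a strictly increasing numeric time header. Files
are plain delimited text: cell (1,1) is the literal ``gene_id``, the rest of
the header row holds the time points, and each subsequent row is one gene.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "read_expression_matrix",
    "write_expression_matrix",
    "filter_zero_variance",
    "standardize_genes",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x timepoints numeric matrix.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per row.
    times
        Strictly increasing observation times (arbitrary units), one per
        column.
    values
        Real matrix of shape ``(len(gene_ids), len(times))``; row ``i`` holds
        the observations of gene ``i``.
    """

    gene_ids: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        gene_ids = tuple(str(g) for g in self.gene_ids)
        times = np.asarray(self.times, dtype=float)
        values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if values.size == 0:
            values = values.reshape(len(gene_ids), len(times))
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)

        if len(set(gene_ids)) != len(gene_ids):
            seen: set[str] = set()
            for g in gene_ids:
                if g in seen:
                    raise ValueError(f"duplicate gene id: {g!r}")
                seen.add(g)
        if values.shape != (len(gene_ids), len(times)):
            raise ValueError(
                f"shape mismatch: {len(gene_ids)} gene ids, {len(times)} times, "
                f"values of shape {values.shape}"
            )
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("time points must be strictly increasing")
        if not np.all(np.isfinite(times)):
            raise ValueError("time points must be finite")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must all be finite")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(gene_ids)})

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return len(self.times)

    def index_of(self, gene_id: str) -> int:
        """Row index of ``gene_id``; raises ``KeyError`` naming the id."""
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"gene id not found: {gene_id!r}") from None

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.index_of(gene_id)]

    def subset(self, gene_ids) -> "ExpressionMatrix":
        """Row-subset in the given order."""
        idx = [self.index_of(g) for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.times, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=list(self.gene_ids), columns=self.times)
        df.index.name = "gene_id"
        return df


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(str(path))[1].lower()
    return "," if ext == ".csv" else "\t"


def read_expression_matrix(path, delimiter: str | None = None) -> ExpressionMatrix:
    """Read a delimited genes x timepoints table.

    The delimiter is auto-detected from the extension (``.csv`` comma,
    anything else tab) unless given explicitly. Errors name the offending
    gene id or cell.
    """
    sep = _delimiter_for(path, delimiter)
    # the header is parsed by hand: pandas would silently de-duplicate
    # repeated time columns, defeating the strictly-increasing check
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    try:
        times = np.asarray([float(c) for c in header[1:]], dtype=float)
    except ValueError as exc:
        raise ValueError(f"header row must be numeric time points: {exc}") from None
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise ValueError("time points in the header must be strictly increasing")
    df = pd.read_csv(
        path, sep=sep, index_col=0, header=None, skiprows=1, dtype=str,
        names=["gene_id"] + list(range(len(times))),
    )
    gene_ids = [str(g) for g in df.index]
    seen: set[str] = set()
    for g in gene_ids:
        if g in seen:
            raise ValueError(f"duplicate gene id: {g!r}")
        seen.add(g)

    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = df[col].astype(float).to_numpy()
        except (ValueError, TypeError):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (ValueError, TypeError):
                    raise ValueError(
                        f"non-numeric cell at gene {gene_ids[i]!r}, "
                        f"time column {col!r}: {cell!r}"
                    ) from None
            raise
    return ExpressionMatrix(tuple(gene_ids), times, values)


def write_expression_matrix(X: ExpressionMatrix, path, delimiter: str | None = None) -> None:
    """Write a matrix so that a read round-trip preserves values exactly.

    Floats are written with shortest round-trip representation.
    """
    sep = _delimiter_for(path, delimiter)
    with open(path, "w") as fh:
        fh.write("gene_id" + sep + sep.join(repr(float(t)) for t in X.times) + "\n")
        for g, row in zip(X.gene_ids, X.values):
            fh.write(g + sep + sep.join(repr(float(v)) for v in row) + "\n")


def filter_zero_variance(X: ExpressionMatrix) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes whose standard deviation is zero.

    Constancy is tested as exact equality of all entries in the row, not a
    tolerance. Returns the filtered matrix and the removed ids in their
    original order.
    """
    if X.n_genes == 0:
        return X, []
    constant = np.all(X.values == X.values[:, :1], axis=1)
    keep = [g for g, c in zip(X.gene_ids, constant) if not c]
    removed = [g for g, c in zip(X.gene_ids, constant) if c]
    return ExpressionMatrix(tuple(keep), X.times, X.values[~constant]), removed


def standardize_genes(X: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene to mean 0 and sample standard deviation 1 (ddof=1)."""
    sd = X.values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = X.gene_ids[int(np.argmax(sd == 0))]
        raise ValueError(
            f"gene {bad!r} has zero variance; run filter_zero_variance first"
        )
    vals = (X.values - X.values.mean(axis=1, keepdims=True)) / sd[:, None]
    return ExpressionMatrix(X.gene_ids, X.times, vals)
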