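"""Core in-memory containers shared across the package.

The pipeline passes three kinds of objects around: a raw count table, a
gene-by-sample expression matrix on some scale (log2-RPKM, standardized,
or PC-residual), and a symmetric gene-gene correlation matrix whose rows
and columns are ordered by a per-gene covariate (mean log-expression).
All containers are thin dataclasses over numpy arrays; pandas is used at
the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountsTable",
    "ExpressionMatrix",
    "CorrelationMatrix",
]

#: allowed values of ExpressionMatrix.scale_tag
SCALE_TAGS = ("log2rpkm", "log2rpm", "standardized", "residual")


@dataclass
class CountsTable:
    """A gene x sample matrix of non-negative integer read counts."""

    gene_ids: list[str]
    counts: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D genes x samples matrix")
        n_genes, n_samples = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError("gene_ids length does not match counts rows")
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length does not match counts columns")
        if n_samples < 2:
            raise ValueError("need at least 2 samples")
        if len(set(self.gene_ids)) != n_genes:
            raise ValueError("duplicate gene_ids")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> np.ndarray:
        """Total reads per sample (column sums)."""
        return self.counts.sum(axis=0)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountsTable":
        """Build from a DataFrame with gene IDs as the index."""
        return cls(
            gene_ids=[str(g) for g in df.index],
            counts=df.to_numpy(),
            sample_ids=[str(s) for s in df.columns],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class ExpressionMatrix:
    """A gene x sample real-valued expression matrix.

    Parameters
    ----------
    gene_ids
        Row identifiers, unique.
    values
        Real matrix, genes x samples.
    scale_tag
        One of ``log2rpkm``, ``log2rpm``, ``standardized``, ``residual``.
    sample_ids
        Optional column identifiers.
    base_mean
        Per-gene mean log-expression *before* any standardization or
        residualization.  Standardized rows all have mean zero, so the
        expression-level covariate used to sort the correlation matrix
        must be carried forward from the log-scale matrix; transforms in
        :mod:`spqn.preprocess` propagate this field.
    """

    gene_ids: list[str]
    values: np.ndarray
    scale_tag: str
    sample_ids: list[str] | None = None
    base_mean: np.ndarray | None = None
    mean_expr: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D genes x samples")
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids length does not match values rows")
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.sample_ids is not None and len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length does not match values columns")
        self.mean_expr = self.values.mean(axis=1)
        if self.base_mean is None and self.scale_tag in ("log2rpkm", "log2rpm"):
            self.base_mean = self.mean_expr.copy()
        if self.base_mean is not None:
            self.base_mean = np.asarray(self.base_mean, dtype=float)
            if self.base_mean.shape != (self.values.shape[0],):
                raise ValueError("base_mean must have one entry per gene")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = self.sample_ids
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


@dataclass
class CorrelationMatrix:
    """A symmetric Pearson correlation matrix sorted by a gene covariate.

    ``covariate`` (mean log-expression) is non-decreasing along the index;
    the matrix rows/columns follow the same order.  The diagonal is exactly 1.
    """

    gene_ids: list[str]
    covariate: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.covariate = np.asarray(self.covariate, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix must be square")
        if len(self.gene_ids) != n or self.covariate.shape != (n,):
            raise ValueError("gene_ids/covariate length mismatch")
        if np.any(np.diff(self.covariate) < 0):
            raise ValueError("matrix must be sorted by covariate")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def validate(self, atol: float = 1e-8) -> None:
        """Check symmetry, unit diagonal and range; raise on violation."""
        v = self.values
        if not np.array_equal(v, v.T):
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=atol):
            raise ValueError("diagonal must be 1")
        if np.any(v < -1 - atol) or np.any(v > 1 + atol):
            raise ValueError("entries outside [-1, 1]")
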