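"""Reading and writing the delimited-text formats used by the pipeline.

Counts: delimited text, header row of sample IDs, first column gene IDs.
Annotation: delimited text with columns gene_id, length_bp, biotype.
Expression / correlation matrices: delimited text in sorted gene order
with a sidecar gene-order file (1-based index, gene_id, covariate);
``.h5`` paths use an HDF5 container instead for large matrices.
All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CorrelationMatrix, CountsTable, ExpressionMatrix

__all__ = [
    "read_counts",
    "read_annotation",
    "write_correlation",
    "read_correlation",
    "write_expression",
    "atomic_write_text",
]


def _read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python", index_col=0)


def atomic_write_text(path: str | Path, text: str) -> None:
    """Write text to ``path`` via a temp file so failures leave no partial file."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_to_csv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", **kwargs))


def read_counts(path: str | Path) -> CountsTable:
    """Read a counts table (tab- or comma-delimited; genes as rows)."""
    df = _read_table(path)
    counts = df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValueError(f"non-numeric entries in counts file {path}")
    if np.any(counts != np.floor(counts)):
        raise ValueError("counts must be integers")
    return CountsTable(
        gene_ids=[str(g) for g in df.index],
        counts=counts.astype(np.int64),
        sample_ids=[str(s) for s in df.columns],
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"gene_id", "length_bp"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation must have columns gene_id, length_bp (got {list(df.columns)})")
    return df


def _gene_order_path(path: Path) -> Path:
    return path.with_name(path.name + ".genes.tsv")


def write_correlation(corr: CorrelationMatrix, path: str | Path) -> None:
    """Write a correlation matrix plus its sidecar gene-order file."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("values", data=corr.values)
            f.create_dataset("gene_ids", data=np.array(corr.gene_ids, dtype="S"))
            f.create_dataset("covariate", data=corr.covariate)
        return
    df = pd.DataFrame(corr.values, index=corr.gene_ids, columns=corr.gene_ids)
    _atomic_to_csv(df, path, index_label="gene_id")
    order = pd.DataFrame(
        {
            "index": np.arange(1, corr.n_genes + 1),
            "gene_id": corr.gene_ids,
            "covariate": corr.covariate,
        }
    )
    _atomic_to_csv(order, _gene_order_path(path), index=False)


def read_correlation(
    path: str | Path, covariate_path: str | Path | None = None
) -> CorrelationMatrix:
    """Read a correlation matrix; genes are re-sorted by covariate if needed.

    The covariate comes from ``covariate_path`` (columns gene_id,
    covariate) or, if omitted, the sidecar gene-order file written by
    :func:`write_correlation`.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as f:
            values = f["values"][:]
            gene_ids = [g.decode() for g in f["gene_ids"][:]]
            covariate = f["covariate"][:]
    else:
        df = _read_table(path)
        values = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        if covariate_path is None:
            covariate_path = _gene_order_path(path)
        cov_df = pd.read_csv(covariate_path, sep=None, engine="python")
        if "gene_id" not in cov_df.columns:
            raise ValueError("covariate file must have a gene_id column")
        cov_col = "covariate" if "covariate" in cov_df.columns else cov_df.columns[-1]
        cov_map = dict(zip(cov_df["gene_id"].astype(str), cov_df[cov_col].astype(float)))
        missing = [g for g in gene_ids if g not in cov_map]
        if missing:
            raise ValueError(f"covariate missing for gene(s): {', '.join(missing[:5])}")
        covariate = np.array([cov_map[g] for g in gene_ids])

    order = sorted(range(len(gene_ids)), key=lambda i: (covariate[i], gene_ids[i]))
    order = np.asarray(order)
    return CorrelationMatrix(
        gene_ids=[gene_ids[i] for i in order],
        covariate=np.asarray(covariate)[order],
        values=values[np.ix_(order, order)],
    )


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    _atomic_to_csv(expr.to_dataframe(), path, index_label="gene_id")
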