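"""Preprocessing: counts -> filtered log-expression -> PC residuals -> correlations.

The standard co-expression pipeline behind the normalization method:

1. convert read counts to log2-RPKM (or log2-RPM),
2. keep genes whose median log-expression exceeds a threshold,
3. standardize each gene to mean 0 / variance 1 across samples,
4. regress out the top-k principal components (unwanted variation),
5. compute the Pearson correlation matrix of the residuals, with genes
   sorted by their mean log-expression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CorrelationMatrix, CountsTable, ExpressionMatrix

__all__ = [
    "compute_log_rpkm",
    "compute_log_rpm",
    "filter_by_median",
    "standardize_genes",
    "remove_top_pcs",
    "correlation_matrix",
]


def _lengths_for(counts: CountsTable, annot: pd.DataFrame) -> np.ndarray:
    """Per-gene lengths (bp) aligned with counts.gene_ids; hard error on gaps."""
    if "gene_id" in annot.columns:
        annot = annot.set_index("gene_id")
    lengths = annot["length_bp"]
    missing = [g for g in counts.gene_ids if g not in lengths.index]
    if missing:
        raise ValueError(f"missing annotation for gene(s): {', '.join(missing[:5])}")
    out = lengths.loc[counts.gene_ids].to_numpy(dtype=float)
    if np.any(out < 1):
        bad = [g for g, l in zip(counts.gene_ids, out) if l < 1]
        raise ValueError(f"gene length must be >= 1 bp: {', '.join(bad[:5])}")
    return out


def compute_log_rpkm(
    counts: CountsTable,
    annot: pd.DataFrame,
    pseudocount: float = 0.5,
    pseudocount_after: bool = False,
) -> ExpressionMatrix:
    """Reads-per-kilobase-per-million on the log2 scale.

    log2((reads + pseudocount) * 1e9 / (library_size * gene_length)), where
    the library size is the total number of reads in the sample.

    With ``pseudocount_after=True`` the pseudocount is applied on the RPKM
    scale instead, log2(RPKM + pseudocount) — the convention used for
    RPKM-normalized single-cell matrices.
    """
    lengths = _lengths_for(counts, annot)
    libsize = counts.library_sizes().astype(float)
    if np.any(libsize <= 0):
        raise ValueError("zero library size")
    denom = np.outer(lengths, libsize)
    if pseudocount_after:
        values = np.log2(counts.counts * 1e9 / denom + pseudocount)
    else:
        values = np.log2((counts.counts + pseudocount) * 1e9 / denom)
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        values=values,
        scale_tag="log2rpkm",
        sample_ids=list(counts.sample_ids),
    )


def compute_log_rpm(counts: CountsTable, pseudocount: float = 0.5) -> ExpressionMatrix:
    """Reads-per-million on the log2 scale (no gene-length normalization)."""
    libsize = counts.library_sizes().astype(float)
    if np.any(libsize <= 0):
        raise ValueError("zero library size")
    values = np.log2((counts.counts + pseudocount) * 1e6 / libsize[None, :])
    return ExpressionMatrix(
        gene_ids=list(counts.gene_ids),
        values=values,
        scale_tag="log2rpm",
        sample_ids=list(counts.sample_ids),
    )


def filter_by_median(expr: ExpressionMatrix, threshold: float = 0.0) -> ExpressionMatrix:
    """Keep genes whose median log-expression is strictly above ``threshold``."""
    medians = np.median(expr.values, axis=1)
    keep = medians > threshold
    if not np.any(keep):
        raise ValueError("no genes pass filter")
    return ExpressionMatrix(
        gene_ids=[g for g, k in zip(expr.gene_ids, keep) if k],
        values=expr.values[keep],
        scale_tag=expr.scale_tag,
        sample_ids=expr.sample_ids,
        base_mean=None if expr.base_mean is None else expr.base_mean[keep],
    )


def standardize_genes(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale each gene row to mean 0, variance 1 (unbiased, n-1 divisor).

    The pre-standardization mean log-expression is preserved in
    ``base_mean`` so it can serve as the sort covariate downstream.
    """
    mu = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        bad = [expr.gene_ids[i] for i in zero[:10]]
        raise ValueError(f"zero-variance gene(s): {', '.join(bad)}")
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        values=(expr.values - mu) / sd,
        scale_tag="standardized",
        sample_ids=expr.sample_ids,
        base_mean=expr.base_mean if expr.base_mean is not None else mu.ravel().copy(),
    )


def remove_top_pcs(expr: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Regress out the top-k principal components from each gene row.

    The components are the top-k right singular vectors of the standardized
    genes x samples matrix (sample-space PCs).  Each gene row is replaced by
    its OLS residual on those vectors; with orthonormal components this is
    the projection ``X - X V_k V_k^T``.  ``k=0`` returns the input unchanged
    apart from the scale tag.
    """
    X = expr.values
    bound = min(X.shape)
    if not 0 <= k < bound:
        raise ValueError(f"k must satisfy 0 <= k < min(n_genes, n_samples) = {bound}")
    if k == 0:
        resid = X.copy()
    else:
        # Vt rows are orthonormal directions in sample space
        _, _, Vt = np.linalg.svd(X, full_matrices=False)
        Vk = Vt[:k]
        resid = X - (X @ Vk.T) @ Vk
    return ExpressionMatrix(
        gene_ids=list(expr.gene_ids),
        values=resid,
        scale_tag="residual",
        sample_ids=expr.sample_ids,
        base_mean=expr.base_mean,
    )


def correlation_matrix(
    expr: ExpressionMatrix,
    sort_covariate: np.ndarray | None = None,
) -> CorrelationMatrix:
    """Pearson correlation of gene rows, sorted by expression level.

    ``sort_covariate`` defaults to the mean log-expression carried in
    ``expr.base_mean`` (the average expression across samples before any
    standardization).  Genes are reordered by covariate ascending, ties
    broken by gene ID, so the matrix is ready for spatial normalization.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for correlations")
    if sort_covariate is None:
        if expr.base_mean is None:
            raise ValueError("no sort covariate available; pass sort_covariate")
        sort_covariate = expr.base_mean
    cov = np.asarray(sort_covariate, dtype=float)
    if cov.shape != (expr.n_genes,) or not np.all(np.isfinite(cov)):
        raise ValueError("sort_covariate must have one finite value per gene")
    sd = expr.values.std(axis=1, ddof=1)
    if np.any(sd == 0):
        bad = [expr.gene_ids[i] for i in np.flatnonzero(sd == 0)[:10]]
        raise ValueError(f"zero-variance residual row(s): {', '.join(bad)}")

    # stable sort by (covariate, gene_id)
    order = sorted(range(expr.n_genes), key=lambda i: (cov[i], expr.gene_ids[i]))
    order = np.asarray(order)
    C = np.corrcoef(expr.values[order])
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)  # enforce exact symmetry
    np.fill_diagonal(C, 1.0)
    return CorrelationMatrix(
        gene_ids=[expr.gene_ids[i] for i in order],
        covariate=cov[order],
        values=C,
    )
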