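"""Diagnostics for the mean-correlation relationship and expression bias.

The mean-correlation relationship is the dependence of the spread of
gene-pair correlations on the expression level of the genes involved —
approximately a function of the *minimum* of the two expression levels.
These diagnostics quantify it on a binned correlation matrix (the "2D
boxplot" of per-submatrix IQRs), split per-bin correlations into
background and candidate signal, and measure the expression bias of
thresholded co-expression networks before and after normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CorrelationMatrix
from .preprocess import correlation_matrix, remove_top_pcs

__all__ = [
    "IqrGrid",
    "BiasReport",
    "BackgroundSummary",
    "iqr_grid",
    "background_signal_split",
    "expression_bias_curve",
    "geneset_edge_change",
    "qq_points",
    "pc_sweep_summary",
]


def _bin_slices(n: int, n_bins: int) -> list[tuple[int, int]]:
    """Equal-size bins over the sorted gene axis; remainder genes to the last."""
    b = n // n_bins
    if b < 2:
        raise ValueError(f"bin with < 2 genes (n={n}, n_bins={n_bins})")
    cuts = [i * b for i in range(n_bins)] + [n]
    return list(zip(cuts[:-1], cuts[1:]))


def _offdiag_values(values: np.ndarray, rows: tuple[int, int], cols: tuple[int, int]) -> np.ndarray:
    r0, r1 = rows
    c0, c1 = cols
    sub = values[r0:r1, c0:c1]
    if rows == cols:
        return sub[np.triu_indices(r1 - r0, k=1)]
    return sub.ravel()


@dataclass
class IqrGrid:
    """Per-submatrix interquartile ranges of a binned correlation matrix."""

    n_bins: int
    iqr: np.ndarray  # n_bins x n_bins, symmetric
    bin_mean_expr: np.ndarray  # per-bin average covariate
    min_expr: np.ndarray  # per-cell min(bin_mean_expr_i, bin_mean_expr_j)


def iqr_grid(corr: CorrelationMatrix, n_bins: int = 10) -> IqrGrid:
    """The 2D boxplot: IQR of each (i, j) submatrix of the sorted matrix.

    Quantiles use linear interpolation between order statistics.  The
    returned ``min_expr`` cell values support plotting IQR against the
    lower of the two bin expression levels.
    """
    slices = _bin_slices(corr.n_genes, n_bins)
    means = np.array([corr.covariate[a:b].mean() for a, b in slices])
    iqr = np.zeros((n_bins, n_bins))
    for i in range(n_bins):
        for j in range(i, n_bins):
            vals = _offdiag_values(corr.values, slices[i], slices[j])
            q25, q75 = np.percentile(vals, [25, 75])
            iqr[i, j] = iqr[j, i] = q75 - q25
    min_expr = np.minimum.outer(means, means)
    return IqrGrid(n_bins=n_bins, iqr=iqr, bin_mean_expr=means, min_expr=min_expr)


def background_signal_split(
    corr: CorrelationMatrix,
    n_bins: int = 10,
    signal_q: float = 0.001,
    absolute: bool = False,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Per diagonal bin: (background, signal) correlations.

    Background is every within-bin gene-pair correlation; signal is its top
    ``signal_q`` fraction (``ceil(signal_q * n)`` values), by signed value
    by default or by magnitude with ``absolute=True``.
    """
    if not 0 < signal_q <= 1:
        raise ValueError("signal_q must lie in (0, 1]")
    out = []
    for a, b in _bin_slices(corr.n_genes, n_bins):
        bg = _offdiag_values(corr.values, (a, b), (a, b))
        k = int(np.ceil(signal_q * bg.size))
        key = np.abs(bg) if absolute else bg
        sig = bg[np.argsort(key, kind="stable")[-k:]]
        out.append((np.sort(bg), np.sort(sig)))
    return out


@dataclass
class BiasReport:
    """Expression bias of a thresholded network at one signal threshold."""

    threshold_q: float
    mean_pair_expr_top: float
    mean_pair_expr_all: float

    @property
    def bias(self) -> float:
        return self.mean_pair_expr_top - self.mean_pair_expr_all


def _upper_triangle(corr: CorrelationMatrix):
    iu = np.triu_indices(corr.n_genes, k=1)
    vals = corr.values[iu]
    pair_expr = (corr.covariate[iu[0]] + corr.covariate[iu[1]]) / 2.0
    return iu, vals, pair_expr


def _top_edge_order(vals: np.ndarray, iu, gene_ids: list[str], absolute: bool) -> np.ndarray:
    """Deterministic edge ranking: value descending, ties by pair ID."""
    key = np.abs(vals) if absolute else vals
    pair_names = np.array([f"{gene_ids[a]}\t{gene_ids[b]}" for a, b in zip(iu[0], iu[1])])
    return np.lexsort((pair_names, -key))


def expression_bias_curve(
    corr: CorrelationMatrix,
    thresholds: list[float],
    absolute: bool = True,
) -> list[BiasReport]:
    """Mean pair-expression of top-q edges vs all pairs, per threshold q.

    The pair expression of an edge is the average covariate of its two
    genes; the bias is how much the selected edges exceed the all-pairs
    mean.  Edges are ranked by absolute correlation by default.
    """
    for q in thresholds:
        if not 0 < q <= 1:
            raise ValueError("thresholds must lie in (0, 1]")
    iu, vals, pair_expr = _upper_triangle(corr)
    order = _top_edge_order(vals, iu, corr.gene_ids, absolute)
    all_mean = float(pair_expr.mean())
    reports = []
    for q in thresholds:
        if q == 1.0:
            top_mean = all_mean  # exact zero bias by construction
        else:
            k = int(np.ceil(q * vals.size))
            top_mean = float(pair_expr[order[:k]].mean())
        reports.append(
            BiasReport(threshold_q=q, mean_pair_expr_top=top_mean, mean_pair_expr_all=all_mean)
        )
    return reports


def geneset_edge_change(
    corr_before: CorrelationMatrix,
    corr_after: CorrelationMatrix,
    geneset: set[str],
    thresholds: list[float],
    absolute: bool = True,
) -> list[float]:
    """Percent change in thresholded edges touching a gene set.

    For each threshold q the top ``ceil(q * n_pairs)`` edges are selected in
    both matrices and the number with at least one endpoint in ``geneset``
    is compared: 100 * (after - before) / before.  NaN where the before
    count is zero.
    """
    if corr_before.gene_ids != corr_after.gene_ids:
        raise ValueError("matrices must cover the same sorted gene set")
    in_set = np.array([g in geneset for g in corr_before.gene_ids])

    def counts(corr: CorrelationMatrix) -> list[int]:
        iu, vals, _ = _upper_triangle(corr)
        order = _top_edge_order(vals, iu, corr.gene_ids, absolute)
        touches = in_set[iu[0]] | in_set[iu[1]]
        ranked = touches[order]
        return [int(ranked[: int(np.ceil(q * vals.size))].sum()) for q in thresholds]

    before = counts(corr_before)
    after = counts(corr_after)
    return [
        100.0 * (ea - eb) / eb if eb > 0 else float("nan") for eb, ea in zip(before, after)
    ]


def qq_points(
    corr: CorrelationMatrix,
    bin_a: tuple[int, int],
    bin_ref: tuple[int, int],
    n_quantiles: int = 100,
    n_bins: int = 10,
) -> np.ndarray:
    """Paired quantiles of two submatrices (Q-Q plot coordinates).

    Bins are 1-based (i, j) cells of an ``n_bins`` x ``n_bins`` partition;
    quantiles are taken at probabilities (k - 0.5)/n_quantiles.  Returns an
    (n_quantiles, 2) array of (reference, other) quantile pairs; a pure
    scale difference between the two distributions shows as a line through
    the origin.
    """
    slices = _bin_slices(corr.n_genes, n_bins)

    def bin_vals(b):
        i, j = b
        if not (1 <= i <= n_bins and 1 <= j <= n_bins):
            raise ValueError(f"bin {b} outside {n_bins}x{n_bins} partition")
        vals = _offdiag_values(corr.values, slices[min(i, j) - 1], slices[max(i, j) - 1])
        if vals.size == 0:
            raise ValueError(f"empty bin {b}")
        return vals

    p = (np.arange(n_quantiles) + 0.5) / n_quantiles * 100
    qa = np.percentile(bin_vals(bin_a), p)
    qr = np.percentile(bin_vals(bin_ref), p)
    return np.column_stack([qr, qa])


@dataclass
class BackgroundSummary:
    """Per-bin background location/spread after removing k PCs."""

    k_pcs_removed: int
    bin_median: np.ndarray  # per diagonal bin median of correlations (bias)
    bin_variance: np.ndarray  # per diagonal bin variance of correlations

    @property
    def mean_bias(self) -> float:
        return float(self.bin_median.mean())

    @property
    def mean_variance(self) -> float:
        return float(self.bin_variance.mean())


def pc_sweep_summary(expr, k_values: list[int], n_bins: int = 10) -> list[BackgroundSummary]:
    """Background bias/variance of diagonal bins as a function of PCs removed.

    For each k: regress out the top-k PCs, recompute the correlation
    matrix, and summarize each diagonal bin's off-diagonal correlations by
    their median (residual unwanted variation shows as nonzero medians) and
    variance.
    """
    out = []
    for k in k_values:
        corr = correlation_matrix(remove_top_pcs(expr, k))
        slices = _bin_slices(corr.n_genes, n_bins)
        med = np.empty(n_bins)
        var = np.empty(n_bins)
        for b, (a0, a1) in enumerate(slices):
            vals = _offdiag_values(corr.values, (a0, a1), (a0, a1))
            med[b] = np.median(vals)
            var[b] = np.var(vals, ddof=1) if vals.size > 1 else 0.0
        out.append(BackgroundSummary(k_pcs_removed=k, bin_median=med, bin_variance=var))
    return out
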