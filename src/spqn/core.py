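"""Spatial quantile normalization (SpQN) of a sorted correlation matrix.

The correlation matrix, with genes ordered by expression level, is covered
by a grid of disjoint inner bins X_ij, each contained in a larger
overlapping outer enclosure Y_ij.  The empirical distribution of the
correlations in Y_ij estimates the local distribution of X_ij; every entry
of X_ij is pushed through that CDF and pulled back through the quantile
function of a common target distribution:

    X~_ij = q_target( F_emp(Y_ij)(X_ij) )

Because adjacent enclosures overlap, the per-bin normalization maps vary
smoothly across the matrix; when the enclosure equals the inner bin the
procedure reduces to classical per-bin quantile normalization.

Geometry.  With ``n_gene`` genes, ``n_group`` bins per axis and enclosure
side ``w``, enclosures are equally spaced at real-valued distance
``d = (n_gene - w) / (n_group - 1)``; enclosure x spans genes
(round((x-1)d), round((x-1)d) + w].  Inner-bin cut points follow
n2(x) = d/2 + w/2 + (x-1)d (rounded half-up), with n1(1) = 0 and
n2(n_group) = n_gene, so the inner bins are disjoint, cover the axis
exactly, and sit centered inside their enclosures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import CorrelationMatrix

__all__ = [
    "EmpiricalDistribution",
    "GridPartition",
    "SpqnConfig",
    "make_grid",
    "cdf_eval",
    "quantile_eval",
    "build_target",
    "spqn_normalize",
]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class EmpiricalDistribution:
    """A sorted sample supporting CDF evaluation and quantile interpolation."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.sort(np.asarray(self.values, dtype=float).ravel())
        if self.values.size < 1:
            raise ValueError("empirical distribution needs at least one value")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    @property
    def m(self) -> int:
        return self.values.size


def cdf_eval(dist: EmpiricalDistribution, x) -> np.ndarray | float:
    """Plotting-position empirical CDF with midrank ties.

    F(x) = (#{v < x} + 0.5 * #{v = x}) / m, clamped to [0.5/m, 1 - 0.5/m]
    so the result is a usable probability for any finite query.
    """
    v = dist.values
    m = dist.m
    xa = np.asarray(x, dtype=float)
    lt = np.searchsorted(v, xa, side="left")
    le = np.searchsorted(v, xa, side="right")
    p = (lt + 0.5 * (le - lt)) / m
    p = np.clip(p, 0.5 / m, 1.0 - 0.5 / m)
    return p if xa.ndim else float(p)


def quantile_eval(dist: EmpiricalDistribution, p) -> np.ndarray | float:
    """Quantile by linear interpolation of order statistics.

    Order statistic k sits at plotting position (k - 0.5)/m; probabilities
    below the first (above the last) position return the sample minimum
    (maximum).
    """
    pa = np.asarray(p, dtype=float)
    if np.any(pa <= 0) or np.any(pa >= 1):
        raise ValueError("probability must lie strictly in (0, 1)")
    m = dist.m
    positions = (np.arange(m) + 0.5) / m
    q = np.interp(pa, positions, dist.values)
    return q if pa.ndim else float(q)


@dataclass
class GridPartition:
    """Inner disjoint bins and outer overlapping enclosures along one axis.

    Intervals are half-open ``(start, stop]`` in 1-based gene coordinates,
    i.e. Python slice ``[start:stop]`` on the sorted matrix.
    """

    n_gene: int
    n_group: int
    w: int
    d: float = field(init=False)
    inner_bounds: list[tuple[int, int]] = field(init=False)
    outer_bounds: list[tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        n, g, w = self.n_gene, self.n_group, self.w
        if g < 2:
            raise ValueError("n_group must be >= 2")
        if w < 2:
            raise ValueError("w must be >= 2")
        if w > n:
            raise ValueError("enclosure larger than matrix")
        if w * g < n:
            raise ValueError("bins cannot be contained in enclosures; increase w or n_group")
        d = (n - w) / (g - 1)
        self.d = d
        self.outer_bounds = []
        for x in range(1, g + 1):
            start = _round_half_up((x - 1) * d)
            self.outer_bounds.append((start, start + w))
        cuts = [0]
        for x in range(1, g):
            cuts.append(_round_half_up(d / 2 + w / 2 + (x - 1) * d))
        cuts.append(n)
        self.inner_bounds = list(zip(cuts[:-1], cuts[1:]))


def make_grid(n_gene: int, n_group: int, w: int) -> GridPartition:
    """Build the SpQN bin geometry; see the module docstring for the rules."""
    return GridPartition(n_gene=n_gene, n_group=n_group, w=w)


def build_target(corr: CorrelationMatrix, n_bins: int = 10) -> EmpiricalDistribution:
    """Default target: the next-to-top diagonal block of a 10x10 partition.

    Genes (already sorted by expression) are split into ``n_bins`` equal
    bins, remainder to the last; the target is the off-diagonal upper
    triangle of the (n_bins-1, n_bins-1) diagonal block — highly expressed
    genes whose observed correlations are least attenuated by measurement
    noise, while avoiding the extreme top bin whose expression range is
    widest.
    """
    n = corr.n_genes
    if n < 2 * n_bins:
        raise ValueError(f"need at least {2 * n_bins} genes to build the target")
    b = n // n_bins
    lo, hi = (n_bins - 2) * b, (n_bins - 1) * b
    if hi - lo < 2:
        raise ValueError("fewer than 2 genes in the target bin")
    block = corr.values[lo:hi, lo:hi]
    vals = block[np.triu_indices(hi - lo, k=1)]
    return EmpiricalDistribution(vals)


@dataclass
class SpqnConfig:
    """Parameters of the normalization.

    ``n_group`` bins per axis with enclosure side ``w`` (defaults 60 and
    400).  ``target`` is either the string ``"grid_9_9_of_10"`` — build the
    default target from the input matrix — or an explicit
    :class:`EmpiricalDistribution` supported on [-1, 1].
    ``exclude_diagonal`` keeps self-correlations out of every empirical
    distribution; the output diagonal is always set to 1.
    """

    n_group: int = 60
    w: int = 400
    target: str | EmpiricalDistribution = "grid_9_9_of_10"
    exclude_diagonal: bool = True

    def __post_init__(self) -> None:
        if self.n_group < 2:
            raise ValueError("n_group must be >= 2")
        if self.w < 2:
            raise ValueError("w must be >= 2")
        if isinstance(self.target, EmpiricalDistribution):
            if self.target.values[0] < -1 or self.target.values[-1] > 1:
                raise ValueError("target support must be contained in [-1, 1]")
        elif self.target != "grid_9_9_of_10":
            raise ValueError(f"unknown target spec {self.target!r}")


def _outer_values(
    values: np.ndarray, rows: tuple[int, int], cols: tuple[int, int], exclude_diagonal: bool
) -> np.ndarray:
    """Correlations of an enclosure; diagonal blocks contribute each
    unordered pair once (upper triangle), off-diagonal blocks contribute
    every cell."""
    r0, r1 = rows
    c0, c1 = cols
    sub = values[r0:r1, c0:c1]
    if rows == cols:
        iu = np.triu_indices(r1 - r0, k=1 if exclude_diagonal else 0)
        return sub[iu]
    if exclude_diagonal:
        # overlapping enclosures can cross the matrix diagonal
        gr = np.arange(r0, r1)[:, None]
        gc = np.arange(c0, c1)[None, :]
        return sub[gr != gc]
    return sub.ravel()


def spqn_normalize(corr: CorrelationMatrix, cfg: SpqnConfig | None = None) -> CorrelationMatrix:
    """Apply spatial quantile normalization to a sorted correlation matrix.

    Every off-diagonal entry of each inner bin is replaced by
    ``quantile_eval(target, cdf_eval(F_emp(enclosure), entry))``; the
    mirrored entry receives the identical value, and the diagonal stays 1.
    Output values lie within the target's support and the map is
    non-decreasing within each inner bin.
    """
    if cfg is None:
        cfg = SpqnConfig()
    n = corr.n_genes
    if np.any(np.diff(corr.covariate) < 0):
        raise ValueError("matrix must be sorted by covariate")
    grid = make_grid(n, cfg.n_group, cfg.w)
    if isinstance(cfg.target, EmpiricalDistribution):
        target = cfg.target
    else:
        target = build_target(corr)

    out = np.array(corr.values, dtype=float, copy=True)
    for i in range(cfg.n_group):
        ir0, ir1 = grid.inner_bounds[i]
        if ir1 <= ir0:
            continue
        for j in range(i, cfg.n_group):
            jc0, jc1 = grid.inner_bounds[j]
            if jc1 <= jc0:
                continue
            ov = _outer_values(
                corr.values, grid.outer_bounds[i], grid.outer_bounds[j], cfg.exclude_diagonal
            )
            if ov.size < 2:
                raise ValueError(f"outer bin ({i + 1},{j + 1}) has fewer than 2 values")
            femp = EmpiricalDistribution(ov)
            block = corr.values[ir0:ir1, jc0:jc1]
            mapped = quantile_eval(target, cdf_eval(femp, block))
            out[ir0:ir1, jc0:jc1] = mapped
            out[jc0:jc1, ir0:ir1] = mapped.T
    np.fill_diagonal(out, 1.0)
    return CorrelationMatrix(
        gene_ids=list(corr.gene_ids), covariate=corr.covariate.copy(), values=out
    )
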