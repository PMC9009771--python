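# Methods

## The measurement model

Observed counts are modeled hierarchically: a gene's true expression `Z`
(linear scale) has mean `E(Z)` and squared coefficient of variation
`CV²(Z)`; the observed count satisfies `E(Y|Z) = Z`, `Var(Y|Z) = Z`
(Poisson sequencing noise), and counts of different genes are
conditionally independent given their true expressions. Under these
assumptions `Cov(Y1, Y2) = Cov(Z1, Z2)`, hence

    Cor(Y1, Y2) = Cor(Z1, Z2) · f1 · f2,
    f = sd(Z)/sd(Y) = sqrt( CV²(Z) / (1/E(Z) + CV²(Z)) ).

`f` rises monotonically in both `E(Z)` and `CV²(Z)` and approaches 1 at
high expression: lowly expressed genes show systematically attenuated
correlations. `spqn.model.verify_identity_mc` checks the identity by
simulation with Gamma marginals (making `Y` negative binomial) coupled
through a Gaussian copula. The copula parameter is calibrated to the
requested latent Pearson correlation by monotone root-finding on a fixed
calibration sample (200 000 draws, tolerance 0.005, deterministic
internal stream, cached per parameter set); both sides of the identity
are then computed from the empirical moments of the *same* simulated
sample, so the reported discrepancy reflects only the
conditional-independence structure, not calibration error. The model is
used for explanation and verification only: correction is performed
non-parametrically by the normalization below, not by analytically
inverting the attenuation.

## Preprocessing

Counts are converted to `log2((reads + 0.5) · 10⁹ / (libsize · length))`
(log2-RPKM; `compute_log_rpm` omits the length term, and a
`pseudocount_after` flag supports the `log2(RPKM + 0.5)` convention of
RPKM-normalized single-cell matrices). Genes with median log-expression
strictly above 0 are kept. Each gene is scaled to mean 0 / variance 1
(unbiased n−1 divisor throughout; correlations are scale-invariant so
the divisor choice is cosmetic, but it is applied consistently).
Unwanted variation is removed by regressing each gene row on the top-k
right singular vectors of the standardized matrix (sample-space PCs);
the number k is supplied by the user. Pearson correlations of the
residual rows form the correlation matrix, with genes sorted by their
mean log-expression *before* standardization (standardized rows all have
mean 0, so the covariate must be carried forward); ties are broken by
gene ID so the ordering is reproducible. The computed matrix is
symmetrized (averaging with its transpose) to guarantee bit-exact
symmetry, clipped to [−1, 1], and its diagonal set to exactly 1.

## The normalization

With `n_gene` sorted genes, `n_group` bins per axis and enclosure side
`w` genes, enclosures are spaced at real-valued distance
`d = (n_gene − w)/(n_group − 1)` with enclosure `x` spanning
`(round((x−1)d), round((x−1)d) + w]` (half-up rounding). Inner-bin cut
points track `n2(x) = d/2 + w/2 + (x−1)d`, rounded half-up, with
`n1(1) = 0` and `n2(n_group) = n_gene`: the inner bins are disjoint,
cover the axis exactly, and (given `d ≤ w`, i.e. `w·n_group ≥ n_gene`)
are provably contained in their enclosures under this rounding since the
real-valued bounds differ by `(w−d)/2 ≥ 0` and rounding is monotone.
When `d < 1` some inner bins may be empty; they are skipped.

Empirical distributions: diagonal blocks contribute each unordered gene
pair once (upper triangle); off-diagonal blocks contribute every cell of
the rectangle (enclosures may overlap the matrix diagonal, whose
self-correlation cells are excluded). The empirical CDF uses midrank
plotting positions, `F(x) = (#{v<x} + 0.5·#{v=x})/m`, clamped to
`[0.5/m, 1 − 0.5/m]`; quantiles interpolate order statistics linearly at
positions `(k − 0.5)/m`, returning the extremes outside the covered
range. These conventions make "source equals target" an exact identity
on distinct values — a testable anchor — and keep all outputs inside the
target's support, hence inside [−1, 1]. Each inner-bin entry is mapped
through its enclosure's CDF into the target's quantiles; the mirrored
entry receives the identical value and the diagonal stays 1. The map is
non-decreasing, so ranks within a bin are preserved.

The default target is the (9,9) diagonal block of a fixed 10×10
partition of the same matrix (remainder genes to the last bin),
regardless of `n_group`: highly expressed genes whose correlations are
least attenuated, avoiding the top bin, which mixes the widest range of
expression values. Any user-supplied distribution supported on [−1, 1]
can replace it.

Defaults `n_group = 60`, `w = 400` suit matrices of ~10 000–13 000
genes, where the enclosure holds ~400 genes per axis and the inner bin
~200. For smaller matrices the same *local sample sizes* matter more
than the bin count; the end-to-end checks on the ~2000-gene fixture use
`n_group = 9`, `w = 400`, which reproduces the ~200/~400 inner/outer
geometry at that size. At `n_group = 60` a 2000-gene matrix would give
inner bins of ~27 genes, too few values for a per-bin distributional
comparison to be meaningful.

## Diagnostics

All diagnostics operate on the expression-sorted matrix with a 10-bin
partition by default (remainder to the last bin) and linear-interpolation
quantiles. The 2D boxplot (`iqr_grid`) reports the IQR of every
(i, j) submatrix together with per-bin mean expression and the per-cell
minimum of the two bin means. `background_signal_split` separates each
diagonal bin's correlations into background and its top fraction
(default 0.1%), by signed value by default — within-bin "signal" is a
one-sided tail — while global edge selection (`expression_bias_curve`,
`geneset_edge_change`) ranks by absolute correlation by default, since
network thresholding treats strong negative edges as signal too; both
choices are flags. Edge selection takes exactly `ceil(q·N)` edges in a
deterministic order (value descending, ties by lexicographic pair ID).
The expression bias at threshold q is the mean pair expression (average
covariate of the two genes) of selected edges minus the all-pairs mean;
at q = 1 it is exactly 0 by construction. `pc_sweep_summary` repeats
residualization and correlation for a list of k values and summarizes
each diagonal bin by the median (residual unwanted variation appears as
nonzero medians) and variance of its correlations.

## Synthetic data

The generator (`spqn.synthetic`) draws a latent Gaussian field with unit
marginals: block factors give within-block correlation `rho_block`
(blocks assigned round-robin across the expression-sorted gene list, so
the true network is expression-independent by construction); optional
shared sample-level factors receive per-gene loadings `~N(0,
batch_strength²)`, a dispersed-sign response that creates a diffuse
background of latent correlations; rows are rescaled to unit variance.
The field is pushed through the Gaussian-copula transform to Gamma
marginals with mean from an even log2 grid over
`mean_log_expr_range` and squared CV `cv2_z`, and counts are drawn as
`Poisson(Z · length · libsize / 10⁹)` with log-uniform gene lengths and
library sizes, mirroring the RPKM convention so log2-RPKM of the counts
recovers the grid. `true_corr` stores the *realized* correlation of the
simulated Z (the copula slightly distorts nominal block correlations),
and `true_edges` the planted block pairs.

Fixture (`mean_correlation_fixture`): 2000 genes × 300 samples, grid
0.5–6.5 log2 units, `cv2_z = 0.3`, 20 blocks of 10 genes at
`rho_block = 0.7`, 30 diffuse factors with loading scale 0.15, gene
lengths 0.5–5 kb, library sizes ~10⁶. These sizes keep expected counts
between ~1 and ~10³, so Poisson noise is comparable to biological
variation at the low end and negligible at the top — the regime in which
the mean-correlation relationship is visible — while the whole pipeline
runs in seconds. The generator does not model single-cell dropout,
library-size-dependent normalization artifacts, or differential
composition between conditions; passing tests demonstrate that the
method removes expression-level bias arising through the Poisson
measurement channel, not that it handles every source of structure in
real data. Pooled-condition settings can be emulated by concatenating
two datasets generated with different expression grids.

## Numerical choices and limitations

- Half-up rounding (`floor(x + 0.5)`) for all grid cut points; the last
  inner bin absorbs the remainder so coverage is exact.
- The enclosure definition includes the first gene of each window
  (half-open `(start, start+w]` after rounding), so every gene belongs
  to at least one enclosure.
- Out-of-range CDF queries clamp to the nearest plotting position;
  quantile queries outside the covered range return the target extrema.
- Correlation matrices are dense `float64`; a 13 000-gene matrix takes
  ~1.3 GB and the normalization sorts each of the `n_group²/2` enclosure
  samples (~`w²` values each), which dominates the run time. No sparse
  or GPU path is provided.
- The method equalizes local distributions; it does not recover the
  latent correlations themselves, and when the true network is
  concentrated among highly expressed genes the re-ranking can
  down-weight genuine high-expression edges. Apply with that trade-off
  in mind.
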