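# spqn — spatial quantile normalization of gene co-expression matrices

In RNA-seq co-expression analysis, the distribution of pairwise Pearson
correlations depends on the expression level of the genes involved: the
spread of correlations grows with expression, approximately as a function
of the *minimum* of the two genes' expression levels. This
*mean-correlation relationship* is a technical artifact of sequencing
noise — under a Gamma-Poisson measurement model with true expression `Z`
and observed counts `Y`,

    Cor(Y1, Y2) = Cor(Z1, Z2) · sd(Z1)/sd(Y1) · sd(Z2)/sd(Y2),
    sd(Z)/sd(Y) = sqrt( CV²(Z) / (1/E(Z) + CV²(Z)) ),

so observed correlations are attenuated copies of the true ones, more
strongly for lowly expressed genes. Thresholding such a matrix to build a
co-expression network preferentially selects highly expressed gene pairs
and misses lowly expressed regulators such as transcription factors.

**Spatial quantile normalization (SpQN)** removes this bias directly on
the correlation matrix. With genes sorted by mean expression, the matrix
is covered by `n_group × n_group` disjoint inner bins `X_ij`, each
centered inside a larger overlapping enclosure `Y_ij` of side `w`
(defaults `n_group = 60`, `w = 400`). Every correlation in `X_ij` is
mapped through the empirical CDF of its enclosure into the quantiles of a
common target distribution:

    X̃_ij = q_target( F_emp(Y_ij)(X_ij) )

The overlap of adjacent enclosures makes the normalization maps vary
smoothly across the matrix; when `Y_ij = X_ij` the method reduces to
classical per-bin quantile normalization. The default target is the
(9,9) diagonal block of a 10×10 partition — highly expressed genes whose
correlations are least attenuated, avoiding the heterogeneous top bin.

The package is aimed at anyone building correlation-based gene networks
(WGCNA-style thresholding, graphical models fed with a correlation or
covariance matrix) from bulk or single-cell RNA-seq. It provides:

- `spqn.preprocess` — counts → log2-RPKM/RPM, median filtering,
  per-gene standardization, removal of top principal components
  (unwanted variation), Pearson correlation of the residuals sorted by
  expression;
- `spqn.core` — the bin geometry, empirical CDF/quantile machinery and
  `spqn_normalize`;
- `spqn.diagnostics` — 2D boxplot of per-submatrix IQRs,
  background/signal splits, pair-expression bias curves, gene-set edge
  changes, Q-Q comparisons, PC-sweep summaries;
- `spqn.model` — the Gamma-Poisson attenuation model and its Monte-Carlo
  verification;
- `spqn.synthetic` — seeded count datasets with known, expression-
  independent true networks;
- a `spqn` command-line tool (`normalize`, `diagnose`, `model`,
  `simulate`).

## Worked example

```python
import numpy as np
from scipy.stats import spearmanr
import spqn

# synthetic dataset: 2000 genes x 300 samples, block-structured true
# network spread evenly across expression levels, Poisson noise
ds = spqn.mean_correlation_fixture(seed=1)

expr = spqn.compute_log_rpkm(ds.counts, ds.annot)     # log2-RPKM
expr = spqn.filter_by_median(expr)                    # median log2-RPKM > 0
corr = spqn.correlation_matrix(spqn.standardize_genes(expr))

grid = spqn.iqr_grid(corr)                            # 10x10 "2D boxplot"
iu = np.triu_indices(10)
print("pre  Spearman(IQR, min expr):",
      round(spearmanr(grid.iqr[iu], grid.min_expr[iu]).statistic, 3))
print("pre  IQR range:", round(grid.iqr.min(), 4), "-", round(grid.iqr.max(), 4))

post = spqn.spqn_normalize(corr, spqn.SpqnConfig(n_group=9, w=400))
gp = spqn.iqr_grid(post)
print("post IQR range:", round(gp.iqr.min(), 4), "-", round(gp.iqr.max(), 4))

pre_b, = spqn.expression_bias_curve(corr, [0.001])
post_b, = spqn.expression_bias_curve(post, [0.001])
print("top-0.1% pair-expression bias:",
      round(pre_b.bias, 3), "->", round(post_b.bias, 3))
```

Output:

```
pre  Spearman(IQR, min expr): 0.929
pre  IQR range: 0.0898 - 0.1216
post IQR range: 0.1146 - 0.1182
top-0.1% pair-expression bias: 0.751 -> 0.045
```

Before normalization the spread of the background correlations tracks the
minimum bin expression almost perfectly (Spearman 0.93) and the strongest
0.1% of edges sit 0.75 log2 units above the average pair expression; after
normalization the IQR grid is nearly flat and the selection bias is ~6% of
its original size, while ranks within every bin are preserved.

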