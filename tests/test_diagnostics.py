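import numpy as np
import pytest

import spqn

from conftest import random_correlation_matrix


def corr_from_values(values, covariate=None, gene_ids=None):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return spqn.CorrelationMatrix(
        gene_ids=gene_ids or [f"g{i:03d}" for i in range(n)],
        covariate=np.arange(n, dtype=float) if covariate is None else np.asarray(covariate, float),
        values=values,
    )


class TestIqrGrid:
    def test_constant_matrix_zero_iqr(self):
        v = np.full((40, 40), 0.2)
        np.fill_diagonal(v, 1.0)
        grid = spqn.iqr_grid(corr_from_values(v), n_bins=4)
        assert np.all(grid.iqr == 0.0)

    def test_normal_entries_match_closed_form(self):
        # IQR of N(0, sigma) is 2 * Phi^-1(0.75) * sigma = 1.349 sigma
        rng = np.random.default_rng(0)
        sigma = 0.1
        n = 200  # diagonal bin holds ~ 5e3 values, plenty for 2% accuracy
        a = rng.normal(0, sigma, size=(n, n))
        v = (a + a.T) / np.sqrt(2)
        np.fill_diagonal(v, 1.0)
        grid = spqn.iqr_grid(corr_from_values(v), n_bins=2)
        np.testing.assert_allclose(grid.iqr, 1.34898 * sigma, rtol=0.05)

    def test_hand_computed_two_bins(self):
        v = np.eye(4)
        pairs = {(0, 1): 0.1, (0, 2): 0.2, (0, 3): 0.3, (1, 2): 0.4, (1, 3): 0.5, (2, 3): 0.6}
        for (i, j), val in pairs.items():
            v[i, j] = v[j, i] = val
        grid = spqn.iqr_grid(corr_from_values(v), n_bins=2)
        # bin (0,0): single value 0.1 -> IQR 0; bin (0,1): values {0.2,0.3,0.4,0.5}
        assert grid.iqr[0, 0] == 0.0
        assert grid.iqr[0, 1] == pytest.approx(np.percentile([0.2, 0.3, 0.4, 0.5], 75)
                                               - np.percentile([0.2, 0.3, 0.4, 0.5], 25))
        assert grid.iqr[1, 1] == 0.0
        np.testing.assert_array_equal(grid.min_expr, np.array([[0.5, 0.5], [0.5, 2.5]]))

    def test_invariant_to_relabeling_within_bin(self):
        rng = np.random.default_rng(1)
        corr = random_correlation_matrix(60, rng)
        corr.covariate = np.repeat(np.arange(6.0), 10)  # ties within each bin
        grid1 = spqn.iqr_grid(corr, n_bins=6)
        # permute genes inside the third bin (rows/cols 20..29)
        perm = np.arange(60)
        perm[20:30] = rng.permutation(perm[20:30])
        corr2 = spqn.CorrelationMatrix(
            gene_ids=[corr.gene_ids[i] for i in perm],
            covariate=corr.covariate[perm],
            values=corr.values[np.ix_(perm, perm)],
        )
        grid2 = spqn.iqr_grid(corr2, n_bins=6)
        np.testing.assert_allclose(grid1.iqr, grid2.iqr, atol=1e-12)


class TestBackgroundSignalSplit:
    def test_signal_q_one_returns_background(self):
        rng = np.random.default_rng(2)
        corr = random_correlation_matrix(40, rng)
        for bg, sig in spqn.background_signal_split(corr, n_bins=4, signal_q=1.0):
            np.testing.assert_array_equal(bg, sig)

    def test_top_fraction_counting(self):
        # 100 within-bin values scaled into [-1, 1]; top 2% = top 2 values
        vals = np.linspace(-0.99, 0.99, 100)
        n = 200
        rng = np.random.default_rng(3)
        v = rng.uniform(-0.01, 0.01, size=(n, n))
        v = (v + v.T) / 2
        # plant the known values into bin 0 (genes 0..99 hold C(100,2) pairs; use first 100 upper pairs)
        iu = np.triu_indices(100, k=1)
        planted = np.full(iu[0].size, -1.0)
        planted[:100] = vals
        v[:100, :100][iu] = planted
        v[:100, :100][(iu[1], iu[0])] = planted
        np.fill_diagonal(v, 1.0)
        corr = corr_from_values(v)
        bg, sig = spqn.background_signal_split(corr, n_bins=2, signal_q=2 / iu[0].size)[0]
        assert sig.size == 2
        np.testing.assert_allclose(sig, [vals[-2], vals[-1]])

    def test_all_equal_bin(self):
        v = np.full((20, 20), 0.5)
        np.fill_diagonal(v, 1.0)
        bg, sig = spqn.background_signal_split(corr_from_values(v), n_bins=2, signal_q=0.1)[0]
        assert np.all(sig == 0.5)

    def test_invalid_signal_q(self):
        rng = np.random.default_rng(4)
        corr = random_correlation_matrix(40, rng)
        with pytest.raises(ValueError):
            spqn.background_signal_split(corr, signal_q=0.0)


class TestExpressionBiasCurve:
    def test_q1_is_exactly_zero(self):
        rng = np.random.default_rng(5)
        corr = random_correlation_matrix(50, rng)
        (report,) = spqn.expression_bias_curve(corr, [1.0])
        assert report.bias == 0.0

    def test_permutation_null_bias_small(self):
        # correlations independent of the covariate: selection is unbiased
        rng = np.random.default_rng(6)
        n = 150
        corr = random_correlation_matrix(n, rng)
        (report,) = spqn.expression_bias_curve(corr, [0.01])
        iu = np.triu_indices(n, k=1)
        pair_expr = (corr.covariate[iu[0]] + corr.covariate[iu[1]]) / 2
        k = int(np.ceil(0.01 * pair_expr.size))
        se = pair_expr.std() / np.sqrt(k)
        assert abs(report.bias) < 3 * se

    def test_perfect_confounding_brute_force(self):
        # correlation equal to pair mean covariate: top edges = top covariate pairs
        n = 30
        cov = np.linspace(0.0, 0.9, n)
        v = (cov[:, None] + cov[None, :]) / 2
        np.fill_diagonal(v, 1.0)
        corr = corr_from_values(v, covariate=cov)
        q = 0.01
        (report,) = spqn.expression_bias_curve(corr, [q])
        iu = np.triu_indices(n, k=1)
        pair = (cov[iu[0]] + cov[iu[1]]) / 2
        k = int(np.ceil(q * pair.size))
        expected = np.sort(pair)[-k:].mean() - pair.mean()
        assert report.bias == pytest.approx(expected, abs=1e-12)


class TestGenesetEdgeChange:
    def test_identity_matrices_zero_change(self):
        rng = np.random.default_rng(7)
        corr = random_correlation_matrix(30, rng)
        changes = spqn.geneset_edge_change(corr, corr, {"G00005", "G00010"}, [0.2, 0.5])
        assert changes == [0.0, 0.0]

    def test_full_geneset_zero_change(self):
        rng = np.random.default_rng(8)
        a = random_correlation_matrix(30, rng)
        b = random_correlation_matrix(30, rng)
        b.gene_ids = list(a.gene_ids)
        b.covariate = a.covariate.copy()
        changes = spqn.geneset_edge_change(a, b, set(a.gene_ids), [0.05])
        assert changes == [0.0]

    def test_five_gene_toy_brute_force(self):
        ids = ["a", "b", "c", "d", "e"]
        before = np.eye(5)
        after = np.eye(5)
        vals_b = {("a", "b"): 0.9, ("a", "c"): 0.8, ("a", "d"): 0.1, ("a", "e"): 0.2,
                  ("b", "c"): 0.7, ("b", "d"): 0.3, ("b", "e"): 0.15,
                  ("c", "d"): 0.05, ("c", "e"): 0.25, ("d", "e"): 0.6}
        vals_a = {("a", "b"): 0.1, ("a", "c"): 0.2, ("a", "d"): 0.9, ("a", "e"): 0.8,
                  ("b", "c"): 0.05, ("b", "d"): 0.85, ("b", "e"): 0.4,
                  ("c", "d"): 0.3, ("c", "e"): 0.35, ("d", "e"): 0.7}
        for (i, j), v in vals_b.items():
            before[ids.index(i), ids.index(j)] = before[ids.index(j), ids.index(i)] = v
        for (i, j), v in vals_a.items():
            after[ids.index(i), ids.index(j)] = after[ids.index(j), ids.index(i)] = v
        cb = corr_from_values(before, gene_ids=ids)
        ca = corr_from_values(after, gene_ids=ids)
        # top-3 edges (q = 0.3 of 10): before {ab, ac, bc}, after {ad, bd, ae}
        # geneset {d, e}: before 0 edges -> undefined; geneset {b}: 2 -> 1
        (nan_change,) = spqn.geneset_edge_change(cb, ca, {"d", "e"}, [0.3])
        assert np.isnan(nan_change)
        (change,) = spqn.geneset_edge_change(cb, ca, {"b"}, [0.3])
        assert change == pytest.approx(100 * (1 - 2) / 2)


class TestQqPoints:
    def test_same_bin_identity_line(self):
        rng = np.random.default_rng(9)
        corr = random_correlation_matrix(60, rng)
        pts = spqn.qq_points(corr, (3, 3), (3, 3), n_quantiles=20)
        np.testing.assert_array_equal(pts[:, 0], pts[:, 1])

    def test_scaled_bins_on_line(self):
        n = 60
        rng = np.random.default_rng(10)
        base = rng.uniform(-0.4, 0.4, size=(n, n))
        v = (base + base.T) / 2
        v[:6, :6] *= 0.5  # bin (1,1) is a scaled copy in distribution terms
        np.fill_diagonal(v, 1.0)
        # construct bin (1,1) as exactly 2x bin (2,2)
        iu = np.triu_indices(6, k=1)
        b22 = v[6:12, 6:12][iu]
        v[:6, :6][iu] = 2 * b22
        v[:6, :6][(iu[1], iu[0])] = 2 * b22
        corr = corr_from_values(np.clip(v, -1, 1))
        pts = spqn.qq_points(corr, (1, 1), (2, 2), n_quantiles=15)
        np.testing.assert_allclose(pts[:, 1], 2 * pts[:, 0], atol=1e-12)

    def test_planted_bins_match_direct_sort(self):
        # 2-bin partition over 10 genes: bin (1,2) is a 5x5 rectangle whose
        # 25 values we plant, bin (2,2) holds C(5,2)=10 planted pairs
        rng = np.random.default_rng(11)
        corr = random_correlation_matrix(10, rng)
        v = corr.values
        rect = rng.uniform(-0.9, 0.9, size=(5, 5))
        v[:5, 5:] = rect
        v[5:, :5] = rect.T
        iu = np.triu_indices(5, k=1)
        diag_vals = rng.uniform(-0.9, 0.9, size=10)
        v[5:, 5:][iu] = diag_vals
        v[5:, 5:][(iu[1], iu[0])] = diag_vals
        np.fill_diagonal(v, 1.0)
        pts = spqn.qq_points(corr, (1, 2), (2, 2), n_quantiles=5, n_bins=2)
        p = [10, 30, 50, 70, 90]
        np.testing.assert_allclose(pts[:, 0], np.percentile(diag_vals, p), atol=1e-12)
        np.testing.assert_allclose(pts[:, 1], np.percentile(rect.ravel(), p), atol=1e-12)


class TestPcSweep:
    def test_planted_factor_bias_shrinks(self):
        # a global factor with same-sign loadings shifts background medians
        # upward; regressing out one PC removes the shift
        rng = np.random.default_rng(21)
        n_genes, n_samples = 120, 100
        factor = rng.standard_normal(n_samples)
        loadings = rng.uniform(0.5, 1.5, size=n_genes)
        values = np.outer(loadings, factor) + rng.standard_normal((n_genes, n_samples))
        expr = spqn.standardize_genes(
            spqn.ExpressionMatrix(
                gene_ids=[f"g{i:03d}" for i in range(n_genes)],
                values=values,
                scale_tag="log2rpkm",
            )
        )
        s0, s1 = spqn.pc_sweep_summary(expr, [0, 1], n_bins=4)
        assert s0.mean_bias > 0.2
        assert abs(s1.mean_bias) < 0.1  # shrinks toward 0

    def test_independent_rows_no_bias(self):
        rng = np.random.default_rng(22)
        expr = spqn.ExpressionMatrix(
            gene_ids=[f"g{i:03d}" for i in range(80)],
            values=rng.normal(size=(80, 200)),
            scale_tag="log2rpkm",
        )
        (summary,) = spqn.pc_sweep_summary(spqn.standardize_genes(expr), [0], n_bins=4)
        assert abs(summary.mean_bias) < 3 / np.sqrt(200)

    def test_small_case_matches_hand_computation(self):
        rng = np.random.default_rng(23)
        expr = spqn.standardize_genes(
            spqn.ExpressionMatrix(
                gene_ids=["a", "b", "c", "d"],
                values=rng.normal(size=(4, 30)),
                scale_tag="log2rpkm",
            )
        )
        (summary,) = spqn.pc_sweep_summary(expr, [0], n_bins=2)
        corr = spqn.correlation_matrix(expr)
        v = corr.values
        bin0 = [v[0, 1]]
        bin1 = [v[2, 3]]
        np.testing.assert_allclose(summary.bin_median, [np.median(bin0), np.median(bin1)])
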