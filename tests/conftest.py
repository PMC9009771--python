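import numpy as np
import pytest

import spqn


def random_correlation_matrix(n: int, rng: np.random.Generator) -> spqn.CorrelationMatrix:
    """A symmetric matrix with unit diagonal and distinct-ish off-diagonal
    entries in (-1, 1), sorted by a monotone covariate."""
    a = rng.uniform(-0.95, 0.95, size=(n, n))
    values = (a + a.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return spqn.CorrelationMatrix(
        gene_ids=[f"G{i:05d}" for i in range(n)],
        covariate=np.sort(rng.normal(size=n)),
        values=values,
    )


@pytest.fixture(scope="session")
def fixture_dataset():
    """The seeded mean-correlation dataset used by the end-to-end checks."""
    return spqn.mean_correlation_fixture(seed=1)


@pytest.fixture(scope="session")
def fixture_pipeline(fixture_dataset):
    """Pre- and post-normalization correlation matrices of the fixture.

    The normalization geometry mirrors the recommended local sample sizes
    (outer ~400x400, inner ~200x200) at this 2000-gene matrix.
    """
    ds = fixture_dataset
    expr = spqn.filter_by_median(spqn.compute_log_rpkm(ds.counts, ds.annot))
    corr = spqn.correlation_matrix(spqn.standardize_genes(expr))
    cfg = spqn.SpqnConfig(n_group=9, w=400)
    post = spqn.spqn_normalize(corr, cfg)
    target = spqn.build_target(corr)
    return {"dataset": ds, "pre": corr, "post": post, "target": target, "cfg": cfg}
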