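"""Seeded synthetic count datasets with known co-expression ground truth.

The generator emulates the structure a co-expression analysis sees in
bulk RNA-seq:

* genes placed on an even grid of mean log2 expression (RPKM-like scale);
* a latent Gaussian field W with unit marginals carrying the true
  dependence: block-structured co-expression (within-block correlation
  ``rho_block``) assigned round-robin over the expression-sorted gene
  list, so the true network is independent of expression level, plus
  optional shared sample-level batch factors with per-gene Gaussian
  loadings of scale ``batch_strength``;
* true expression Z with Gamma marginals (mean from the grid, squared
  coefficient of variation ``cv2_z``) obtained by mapping W through the
  Gaussian-copula transform;
* observed counts Y[g, s] ~ Poisson(Z[g, s] * length[g] * libsize[s] / 1e9),
  mirroring the RPKM convention so the log2-RPKM of the counts recovers
  the expression grid.

Because Poisson noise dominates at low expression, the observed
correlations of lowly expressed genes are attenuated copies of the latent
ones — the mechanism behind the mean-correlation relationship the rest of
the package measures and removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CorrelationMatrix, CountsTable

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_dataset", "mean_correlation_fixture"]


@dataclass
class SyntheticConfig:
    """Settings of the generator; defaults give the standard test fixture.

    ``n_batch_factors`` shared sample-level factors receive per-gene
    loadings drawn from N(0, batch_strength^2): dispersed-sign responses
    that create a diffuse background of latent correlations, attenuated by
    sequencing noise at low expression.  ``batch_strength = 0`` disables
    them.
    """

    n_genes: int = 2000
    n_samples: int = 300
    mean_log_expr_range: tuple[float, float] = (0.5, 6.5)
    cv2_z: float = 0.3
    n_blocks: int = 20
    block_size: int = 10
    rho_block: float = 0.7
    batch_strength: float = 0.0
    n_batch_factors: int = 1
    gene_length_range: tuple[float, float] = (500.0, 5000.0)
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks * self.block_size > self.n_genes:
            raise ValueError("n_blocks * block_size exceeds n_genes")
        if not 0.0 <= self.rho_block < 1.0:
            raise ValueError("rho_block must lie in [0, 1)")
        if self.batch_strength < 0:
            raise ValueError("batch_strength must be >= 0")
        if self.cv2_z <= 0:
            raise ValueError("cv2_z must be > 0")


@dataclass
class SyntheticDataset:
    """Counts plus the ground truth they were generated from."""

    counts: CountsTable
    annot: pd.DataFrame
    true_corr: CorrelationMatrix
    true_edges: set[tuple[str, str]]
    batch_factors: np.ndarray  # (n_batch_factors, n_samples)
    mean_z: np.ndarray  # per-gene E(Z), linear RPKM-like scale
    block_of: dict[str, int] = field(default_factory=dict)


def _block_assignment(cfg: SyntheticConfig) -> np.ndarray:
    """Block index per gene (-1 = none); members spread round-robin across
    the expression-sorted gene list so every block spans all levels."""
    n_members = cfg.n_blocks * cfg.block_size
    block = np.full(cfg.n_genes, -1, dtype=int)
    if n_members == 0:
        return block
    member_pos = np.linspace(0, cfg.n_genes - 1, n_members).round().astype(int)
    member_pos = np.unique(member_pos)
    # guard against collisions when n_members approaches n_genes
    while member_pos.size < n_members:
        extra = np.setdiff1d(np.arange(cfg.n_genes), member_pos)[: n_members - member_pos.size]
        member_pos = np.union1d(member_pos, extra)
    block[member_pos] = np.arange(member_pos.size) % cfg.n_blocks
    return block


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Draw one dataset; deterministic given the config (incl. its seed)."""
    rng = np.random.default_rng(cfg.seed)
    n_g, n_s = cfg.n_genes, cfg.n_samples

    lo, hi = cfg.mean_log_expr_range
    mean_z = 2.0 ** np.linspace(lo, hi, n_g)  # genes already expression-sorted
    gene_ids = [f"G{i:05d}" for i in range(n_g)]
    lengths = np.exp(rng.uniform(*np.log(cfg.gene_length_range), size=n_g))
    libsizes = np.exp(rng.uniform(*np.log(cfg.libsize_range), size=n_s))

    block = _block_assignment(cfg)

    # latent Gaussian field, unit marginal variance
    idio = rng.standard_normal((n_g, n_s))
    W = idio.copy()
    if cfg.n_blocks > 0 and cfg.rho_block > 0:
        shared = rng.standard_normal((cfg.n_blocks, n_s))
        in_block = block >= 0
        W[in_block] = (
            np.sqrt(cfg.rho_block) * shared[block[in_block]]
            + np.sqrt(1.0 - cfg.rho_block) * idio[in_block]
        )
    factors = rng.standard_normal((cfg.n_batch_factors, n_s))
    if cfg.batch_strength > 0:
        loadings = rng.normal(0.0, cfg.batch_strength, size=(n_g, cfg.n_batch_factors))
        W = W + loadings @ factors
        W /= np.sqrt(1.0 + (loadings**2).sum(axis=1))[:, None]

    # Gamma marginals via the copula transform
    shape = 1.0 / cfg.cv2_z
    scale = mean_z * cfg.cv2_z  # per gene
    Z = stats.gamma.ppf(stats.norm.cdf(W), a=shape, scale=scale[:, None])

    rate = Z * lengths[:, None] * libsizes[None, :] / 1e9
    counts = rng.poisson(rate)

    annot = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "length_bp": np.maximum(1, lengths.round().astype(int)),
            "biotype": "protein_coding",
        }
    )
    true_corr_values = np.corrcoef(Z)
    true_corr_values = np.clip((true_corr_values + true_corr_values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(true_corr_values, 1.0)
    true_corr = CorrelationMatrix(
        gene_ids=list(gene_ids),
        covariate=np.log2(mean_z),
        values=true_corr_values,
    )
    edges = set()
    for b in range(cfg.n_blocks):
        members = [gene_ids[i] for i in np.flatnonzero(block == b)]
        for a in range(len(members)):
            for c in range(a + 1, len(members)):
                edges.add((members[a], members[c]))
    return SyntheticDataset(
        counts=CountsTable(
            gene_ids=list(gene_ids),
            counts=counts,
            sample_ids=[f"S{j:04d}" for j in range(n_s)],
        ),
        annot=annot,
        true_corr=true_corr,
        true_edges=edges,
        batch_factors=factors,
        mean_z=mean_z,
        block_of={gene_ids[i]: int(b) for i, b in enumerate(block) if b >= 0},
    )


def mean_correlation_fixture(cfg: SyntheticConfig | None = None, seed: int = 1) -> SyntheticDataset:
    """Preset dataset exhibiting the mean-correlation relationship.

    On top of the default expression-independent block network, a diffuse
    layer of 30 shared factors with loading scale 0.15 gives every gene
    pair a small latent correlation; Poisson noise attenuates it at low
    expression, so the background IQR of the binned correlation matrix
    rises with the minimum bin expression level — the pattern the spatial
    normalization is designed to remove.
    """
    if cfg is None:
        cfg = SyntheticConfig()
    cfg = replace(cfg, batch_strength=0.15, n_batch_factors=30, seed=seed)
    return generate_dataset(cfg)
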