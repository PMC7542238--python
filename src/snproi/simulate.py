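"""ADNI-scale synthetic genotype/phenotype generator with block LD structure.

Real candidate-SNP panels show linkage disequilibrium (LD): nearby SNPs are
correlated in blocks. The generator emulates this with a latent-Gaussian
threshold model: within each block, latent variables share an exchangeable
correlation ``within_block_rho``; each latent coordinate is cut at the
Hardy-Weinberg quantiles of a per-SNP minor-allele frequency (drawn uniformly
from ``maf_range``) to produce additive codes {0, 1, 2}. Blocks are
independent, so between-block r^2 is near zero while within-block r^2 is
tunable through rho.

Phenotypes follow a group-row-sparse linear model: ``n_active_groups`` blocks
are active; their weight rows are i.i.d. normal scaled by ``effect_scale``;
all other rows of the true weight matrix are exactly zero. Each ROI's signal
is W*^T (X - mean); with ``link='quadratic'`` a squared term is added so the
SNP->ROI map is genuinely nonlinear. Gaussian noise is scaled per ROI so that
Var(signal)/Var(noise) equals ``snr``, and a per-ROI positive baseline offset
(uniform on [10, 20]) keeps phenotype values strictly positive, as real ROI
volumes and thicknesses are.

The default configuration mirrors the study scale of 632 samples x 486 SNPs
x 56 ROIs with 40 LD blocks. Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .clustering import SNPGroups
from .io import GenotypeMatrix, PhenotypeMatrix


@dataclass
class SimulationConfig:
    n_samples: int = 632
    p_snps: int = 486
    q_rois: int = 56
    n_blocks: int = 40
    within_block_rho: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_active_groups: int = 3
    effect_scale: float = 1.0
    snr: float = 5.0
    link: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_active_groups > self.n_blocks:
            raise ValueError("n_active_groups cannot exceed n_blocks")
        if self.link not in ("linear", "quadratic"):
            raise ValueError("link must be 'linear' or 'quadratic'")
        if self.n_blocks > self.p_snps:
            raise ValueError("more blocks than SNPs")

    def block_labels(self) -> np.ndarray:
        """SNP -> block assignment; remainder SNPs go to the last block."""
        base = self.p_snps // self.n_blocks
        labels = np.repeat(np.arange(self.n_blocks), base)
        if labels.size < self.p_snps:
            labels = np.concatenate([
                labels, np.full(self.p_snps - labels.size, self.n_blocks - 1)])
        return labels


@dataclass
class SyntheticDataset:
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeMatrix
    true_W: np.ndarray
    true_groups: SNPGroups
    active_groups: np.ndarray
    noise_sd: np.ndarray
    baseline: np.ndarray
    mafs: np.ndarray
    config: SimulationConfig

    @property
    def true_support(self) -> np.ndarray:
        """Indices of SNPs with nonzero true effect rows."""
        return np.flatnonzero(np.linalg.norm(self.true_W, axis=1) > 0)


def simulate_genotypes(cfg: SimulationConfig, rng: np.random.Generator | None = None,
                       return_mafs: bool = False):
    """Block-LD genotype matrix via the latent-Gaussian threshold model."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    labels = cfg.block_labels()
    mafs = rng.uniform(*cfg.maf_range, size=cfg.p_snps)
    X = np.empty((cfg.n_samples, cfg.p_snps), dtype=np.int64)
    rho = cfg.within_block_rho
    for b in range(cfg.n_blocks):
        idx = np.flatnonzero(labels == b)
        m = idx.size
        # exchangeable correlation: sqrt(rho) * shared + sqrt(1-rho) * idiosyncratic
        shared = rng.standard_normal((cfg.n_samples, 1))
        own = rng.standard_normal((cfg.n_samples, m))
        Z = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * own
        for j_local, j in enumerate(idx):
            maf = mafs[j]
            # Hardy-Weinberg genotype cdf cut points for the minor allele
            c0 = norm.ppf((1.0 - maf) ** 2)
            c1 = norm.ppf((1.0 - maf) ** 2 + 2.0 * maf * (1.0 - maf))
            z = Z[:, j_local]
            X[:, j] = np.where(z < c0, 0, np.where(z < c1, 1, 2))
    g = GenotypeMatrix(
        X,
        snp_ids=[f"rs{j:06d}" for j in range(cfg.p_snps)],
        sample_ids=[f"S{i:05d}" for i in range(cfg.n_samples)],
        gene_of={f"rs{j:06d}": f"GENE{labels[j]:03d}" for j in range(cfg.p_snps)},
    )
    return (g, mafs) if return_mafs else g


def simulate_dataset(cfg: SimulationConfig) -> SyntheticDataset:
    """Full genotype + group-sparse phenotype dataset; deterministic given seed."""
    rng = np.random.default_rng(cfg.seed)
    g, mafs = simulate_genotypes(cfg, rng=rng, return_mafs=True)
    labels = cfg.block_labels()
    active = np.sort(rng.choice(cfg.n_blocks, size=cfg.n_active_groups, replace=False))
    W = np.zeros((cfg.p_snps, cfg.q_rois))
    active_rows = np.isin(labels, active)
    W[active_rows] = cfg.effect_scale * rng.standard_normal(
        (int(active_rows.sum()), cfg.q_rois))
    Xc = g.values.astype(float) - g.values.mean(axis=0)
    Z = Xc @ W  # n x q linear signal
    if cfg.link == "quadratic":
        sd = Z.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        Zs = Z / sd
        signal = sd * (Zs + 0.5 * (Zs**2 - (Zs**2).mean(axis=0)))
    else:
        signal = Z
    sig_var = signal.var(axis=0, ddof=0)
    noise_sd = np.sqrt(np.where(sig_var > 0, sig_var / cfg.snr, 1.0))
    noise = noise_sd * rng.standard_normal((cfg.n_samples, cfg.q_rois))
    baseline = rng.uniform(10.0, 20.0, size=cfg.q_rois)
    Y = baseline + signal + noise
    ph = PhenotypeMatrix(
        Y, roi_ids=[f"ROI{j:03d}" for j in range(cfg.q_rois)],
        sample_ids=list(g.sample_ids))
    return SyntheticDataset(g, ph, W, SNPGroups(labels), active, noise_sd,
                            baseline, mafs, cfg)
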