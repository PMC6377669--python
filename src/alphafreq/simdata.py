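"""Synthetic genotype and phenotype generation under the alpha model.

Generates dosage panels with a rare-variant-skewed MAF spectrum and local LD
(Gaussian copula haplotype model), optional calibrated imputation noise, and
phenotypes whose per-allele effect variance follows

    Var(beta_j | p_j, LLD_j) = sigma_g_alpha^2 * [2 p_j (1 - p_j)]^alpha
                               * max(0, 1 + tau_star * LLD_j)

with environmental noise scaled to a target heritability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "GenotypePanel",
    "SimConfig",
    "TraitSim",
    "simulate_genotypes",
    "add_imputation_noise",
    "simulate_phenotype",
    "truncate_effects_below_T",
]


@dataclass
class GenotypePanel:
    """Dosage matrix with per-SNP metadata.

    dosages : (N, M) expected minor-allele counts in [0, 2]
    maf     : (M,) minor allele frequencies in (0, 0.5], computed from dosages
    positions : (M,) increasing 1-based physical positions
    probs   : optional (N, M, 3) genotype probability triples (hom-ref, het,
              hom-alt on the minor-allele orientation), each summing to 1
    """

    dosages: np.ndarray
    maf: np.ndarray
    positions: np.ndarray
    probs: Optional[np.ndarray] = None
    sample_ids: Optional[Sequence[str]] = None
    snp_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)
        self.positions = np.asarray(self.positions)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be an N x M matrix")
        n, m = self.dosages.shape
        if self.maf.shape != (m,) or self.positions.shape != (m,):
            raise ValueError("maf and positions must have length M")
        if self.sample_ids is None:
            self.sample_ids = [f"sample_{i}" for i in range(n)]
        if self.snp_ids is None:
            self.snp_ids = [f"snp_{j}" for j in range(m)]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        """Return a panel restricted to SNPs where ``mask`` is True."""
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return GenotypePanel(
            dosages=self.dosages[:, idx],
            maf=self.maf[idx],
            positions=self.positions[idx],
            probs=None if self.probs is None else self.probs[:, idx, :],
            sample_ids=self.sample_ids,
            snp_ids=[self.snp_ids[j] for j in idx],
        )


@dataclass
class SimConfig:
    """Settings for one synthetic genotype/phenotype study."""

    n_samples: int = 1000
    n_snps: int = 8000
    alpha: float = -0.3
    h2: float = 0.4
    prop_causal: float = 0.01
    tau_star: float = 0.0
    imputation_noise: bool = False
    imputation_calibration: float = 0.8
    maf_floor: float = 0.0007
    ld_decay_kb: float = 25.0
    mean_spacing_bp: float = 1000.0
    t_sim: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 < self.prop_causal <= 1.0:
            raise ValueError("prop_causal must be in (0, 1]")
        if not 0.0 < self.maf_floor < 0.5:
            raise ValueError("maf_floor must be in (0, 0.5)")
        if not 0.0 <= self.t_sim < 0.5:
            raise ValueError("t_sim must be in [0, 0.5)")


@dataclass
class TraitSim:
    """One simulated trait: phenotype, true effects and noise level."""

    phenotype: np.ndarray
    beta: np.ndarray
    causal_mask: np.ndarray
    sigma_g_alpha2: float
    sigma_eps2: float
    realized_h2: float = field(default=np.nan)


def _draw_maf_spectrum(rng: np.random.Generator, m: int, floor: float) -> np.ndarray:
    """Sample population MAFs from a 1/p density truncated to [floor, 0.5]."""
    u = rng.random(m)
    return floor * (0.5 / floor) ** u


def _ar1_scan(noise: np.ndarray, phi: np.ndarray, block: int = 128) -> np.ndarray:
    """Stationary AR(1) scan z_j = phi_j z_{j-1} + sqrt(1-phi_j^2) e_j with
    per-step coefficients, evaluated blockwise as a matrix product: within a
    block, z_j = (prod phi) * z_start + sum_i (prod_{l>i} phi_l) g_i e_i, so
    the innovations enter through a triangular transfer matrix."""
    n, m = noise.shape
    z = np.empty_like(noise)
    z[:, 0] = noise[:, 0]
    phi = np.clip(phi, 1e-30, 1.0)  # log-safe; 1e-30 is an effective reset
    g = np.sqrt(1.0 - phi * phi)
    for a in range(1, m, block):
        b = min(a + block, m)
        w = b - a
        lcp = np.cumsum(np.log(phi[a - 1 : b - 1]))  # lcp[t] = log prod to a+t
        j_rel, i_rel = np.meshgrid(np.arange(w), np.arange(w))
        # exponent <= 0 on the used (upper) triangle; clip the unused one
        T = np.where(
            j_rel >= i_rel, np.exp(np.minimum(lcp[j_rel] - lcp[i_rel], 0.0)), 0.0
        )
        T *= g[a - 1 : b - 1, None]
        z[:, a:b] = noise[:, a:b] @ T + np.outer(z[:, a - 1], np.exp(lcp))
    return z


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a dosage panel with rare-variant MAF spectrum and local LD.

    Haplotypes are generated from a Gaussian AR(1) copula: the latent score at
    SNP j correlates with SNP j-1 as exp(-d_j / ld_decay), so physically close
    SNPs are in LD and the decay scale is a single knob (``ld_decay_kb``;
    0 disables LD). Sample-monomorphic draws are forced to carry one
    heterozygote so every column is polymorphic.
    """
    n, m = config.n_samples, config.n_snps
    if n <= 0 or m <= 0:
        raise ValueError("n_samples and n_snps must be positive")
    rng = np.random.default_rng(config.seed)

    p_pop = _draw_maf_spectrum(rng, m, config.maf_floor)
    spacing = np.maximum(
        1, rng.exponential(config.mean_spacing_bp, size=m).astype(np.int64)
    )
    positions = np.cumsum(spacing)

    # latent AR(1) scores per haplotype, z_j = phi_j z_{j-1} + sqrt(1-phi_j^2) e_j
    if config.ld_decay_kb > 0:
        phi = np.exp(-spacing[1:] / (config.ld_decay_kb * 1000.0))
    else:
        phi = np.zeros(m - 1)
    noise = rng.standard_normal((2 * n, m))
    z = _ar1_scan(noise, phi)

    thresh = norm.ppf(p_pop)
    alleles = (z < thresh[None, :]).astype(np.int8)
    geno = alleles[0::2] + alleles[1::2]  # (N, M) in {0,1,2}

    # force sample polymorphism (rare columns can come out monomorphic)
    counts = geno.sum(axis=0)
    mono = np.flatnonzero((counts == 0) | (counts == 2 * n))
    for j in mono:
        i = rng.integers(n)
        geno[i, j] = 1 if counts[j] == 0 else 1

    dosages = geno.astype(float)
    maf = dosages.mean(axis=0) / 2.0
    flip = maf > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    maf = np.where(flip, 1.0 - maf, maf)

    return GenotypePanel(dosages=dosages, maf=maf, positions=positions)


def add_imputation_noise(
    panel: GenotypePanel, calibration: float = 0.8, seed: Optional[int] = None
) -> GenotypePanel:
    """Attach calibrated genotype probabilities and replace dosages by their mean.

    Probabilities are built by blending the hard genotype (one-hot) with a
    Hardy-Weinberg prior at weight ``1 - calibration``; they are calibrated by
    construction (the expected genotype under the triple equals the stored
    dosage). Downstream phenotype simulation draws hard genotypes from the
    triples, while inference keeps using the dosages, mimicking analyses of
    imputed data.
    """
    if not 0.0 < calibration <= 1.0:
        raise ValueError("calibration must be in (0, 1]")
    hard = np.rint(panel.dosages).astype(np.int8)
    if not np.allclose(panel.dosages, hard):
        raise ValueError("panel dosages must be hard genotype calls")
    n, m = hard.shape
    p = panel.maf
    hwe = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)  # (M, 3)
    onehot = np.zeros((n, m, 3), dtype=np.float32)
    rows, cols = np.indices(hard.shape, sparse=True)
    onehot[rows, cols, hard] = 1.0
    probs = calibration * onehot + (1.0 - calibration) * hwe[None, :, :].astype(
        np.float32
    )
    dosages = probs[..., 1] + 2.0 * probs[..., 2]
    maf = dosages.mean(axis=0) / 2.0
    return GenotypePanel(
        dosages=np.asarray(dosages, dtype=float),
        maf=np.minimum(maf, 1.0 - maf),
        positions=panel.positions,
        probs=probs,
        sample_ids=panel.sample_ids,
        snp_ids=panel.snp_ids,
    )


def sample_hard_genotypes(
    panel: GenotypePanel, rng: np.random.Generator
) -> np.ndarray:
    """Draw one hard genotype per individual/SNP from the probability triples."""
    if panel.probs is None:
        raise ValueError("panel carries no genotype probabilities")
    u = rng.random(panel.probs.shape[:2])
    c0 = panel.probs[..., 0]
    c1 = c0 + panel.probs[..., 1]
    return (u >= c0).astype(float) + (u >= c1)


def _effect_variance_weights(
    maf: np.ndarray,
    alpha: float,
    lld: Optional[np.ndarray],
    tau_star: float,
    t_sim: float,
) -> np.ndarray:
    p = np.asarray(maf, dtype=float)
    if t_sim > 0:
        p = np.where(p <= t_sim, t_sim, p)
    w = (2.0 * p * (1.0 - p)) ** alpha
    if tau_star != 0.0:
        if lld is None:
            raise ValueError("tau_star != 0 requires an LLD vector")
        w = w * np.clip(1.0 + tau_star * np.asarray(lld, dtype=float), 0.0, None)
    return w


def simulate_phenotype(
    panel: GenotypePanel,
    config: SimConfig,
    lld: Optional[np.ndarray] = None,
    seed: Optional[int] = None,
) -> TraitSim:
    """Draw causal effects under the alpha model and build a phenotype.

    Causal SNPs are chosen uniformly at random at rate ``prop_causal``. When
    ``config.imputation_noise`` is set and the panel carries probability
    triples, the genotypes entering the genetic value are drawn from the
    triples (the dosages stay untouched for inference). The environmental
    variance is set from the realized genetic variance so the trait hits the
    requested h2. SNPs with zero dosage variance are never causal.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n, m = panel.n_samples, panel.n_snps

    w = _effect_variance_weights(
        panel.maf, config.alpha, lld, config.tau_star, config.t_sim
    )
    causal = rng.random(m) < config.prop_causal
    # never assign effects to sample-monomorphic SNPs
    causal &= panel.dosages.std(axis=0) > 0
    if not causal.any():
        causal[rng.integers(m)] = True

    beta = np.zeros(m)
    beta[causal] = rng.standard_normal(causal.sum()) * np.sqrt(w[causal])

    if config.h2 == 0.0:
        beta[:] = 0.0
        eps = rng.standard_normal(n)
        y = eps - eps.mean()
        return TraitSim(y, beta, causal, 1.0, 1.0, 0.0)

    if config.imputation_noise and panel.probs is not None:
        geno = sample_hard_genotypes(panel, rng)
    else:
        geno = panel.dosages
    g = (geno - geno.mean(axis=0)) @ beta
    var_g = g.var()
    sigma_eps2 = var_g * (1.0 - config.h2) / config.h2
    eps = rng.standard_normal(n) * np.sqrt(sigma_eps2)
    y = g + eps
    y = y - y.mean()
    realized = var_g / y.var() if y.var() > 0 else np.nan
    return TraitSim(y, beta, causal, 1.0, sigma_eps2, realized)


def truncate_effects_below_T(
    betas: np.ndarray, maf: np.ndarray, t_sim: float, alpha: float
) -> np.ndarray:
    """Freeze effect-size variance below a MAF threshold.

    For SNPs with MAF <= t_sim the alpha-model variance is replaced by its
    value at p = t_sim, i.e. each beta is rescaled by
    sqrt([2 t (1-t)]^alpha / [2 p (1-p)]^alpha). t_sim = 0 is a no-op.
    """
    if not 0.0 <= t_sim < 0.5:
        raise ValueError("t_sim must be in [0, 0.5)")
    betas = np.asarray(betas, dtype=float)
    if t_sim == 0.0:
        return betas.copy()
    p = np.asarray(maf, dtype=float)
    scale = np.ones_like(p)
    low = p <= t_sim
    num = (2.0 * t_sim * (1.0 - t_sim)) ** alpha
    den = (2.0 * p[low] * (1.0 - p[low])) ** alpha
    scale[low] = np.sqrt(num / den)
    return betas * scale
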