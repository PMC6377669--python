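"""Synthetic genotype/phenotype generator: determinism, spectra, noise model."""

import numpy as np
import pytest

from alphafreq import (
    SimConfig,
    add_imputation_noise,
    simulate_genotypes,
    simulate_phenotype,
    truncate_effects_below_T,
)
from alphafreq.simdata import _effect_variance_weights, sample_hard_genotypes


def test_seeded_determinism():
    cfg = SimConfig(n_samples=100, n_snps=50, seed=1)
    a, b = simulate_genotypes(cfg), simulate_genotypes(cfg)
    assert np.array_equal(a.dosages, b.dosages)
    assert np.array_equal(a.positions, b.positions)
    ta = simulate_phenotype(a, cfg)
    tb = simulate_phenotype(b, cfg)
    assert np.array_equal(ta.phenotype, tb.phenotype)


def test_maf_consistency_and_floor(small_panel):
    # stored maf equals dosage-derived maf, minor-allele oriented
    maf = small_panel.dosages.mean(axis=0) / 2
    assert np.allclose(small_panel.maf, maf, atol=1e-12)
    assert small_panel.maf.min() > 0
    assert small_panel.maf.max() <= 0.5
    with pytest.raises(ValueError):
        SimConfig(maf_floor=0.0)
    with pytest.raises(ValueError):
        SimConfig(maf_floor=0.6)


def test_rare_skewed_spectrum():
    cfg = SimConfig(n_samples=4000, n_snps=2000, seed=3, ld_decay_kb=0.0)
    panel = simulate_genotypes(cfg)
    # 1/p density: half of the log-range below sqrt(floor * 0.5)
    assert np.median(panel.maf) < 0.05


def test_ld_knob_zero_gives_independence():
    cfg = SimConfig(
        n_samples=400, n_snps=60, seed=5, ld_decay_kb=0.0, maf_floor=0.05
    )
    panel = simulate_genotypes(cfg)
    Z = (panel.dosages - panel.dosages.mean(0)) / panel.dosages.std(0)
    R = Z.T @ Z / panel.n_samples
    off = R[np.triu_indices_from(R, k=1)] ** 2
    # brute-force mean off-diagonal r^2 ~ 1/(n-1) under independence
    assert abs(off.mean() - 1 / (panel.n_samples - 1)) < 1.5 / (panel.n_samples - 1)


def test_ld_knob_positive_creates_local_ld():
    cfg = SimConfig(
        n_samples=400, n_snps=60, seed=5, ld_decay_kb=50.0,
        mean_spacing_bp=200.0, maf_floor=0.05,
    )
    panel = simulate_genotypes(cfg)
    Z = (panel.dosages - panel.dosages.mean(0)) / panel.dosages.std(0)
    r_adj = np.mean(
        [np.corrcoef(Z[:, j], Z[:, j + 1])[0, 1] ** 2 for j in range(59)]
    )
    assert r_adj > 0.3


def test_imputation_noise_calibration(rng):
    cfg = SimConfig(n_samples=60, n_snps=40, seed=7, maf_floor=0.05)
    panel = simulate_genotypes(cfg)

    # degenerate probabilities: sampled genotypes equal dosages exactly
    degen = add_imputation_noise(panel, calibration=1.0)
    assert np.allclose(sample_hard_genotypes(degen, rng), degen.dosages)

    noisy = add_imputation_noise(panel, calibration=0.7)
    assert np.allclose(noisy.probs.sum(axis=-1), 1.0, atol=1e-6)
    # dosage equals the expectation under the probability triple
    exp = noisy.probs[..., 1] + 2 * noisy.probs[..., 2]
    assert np.allclose(noisy.dosages, exp, atol=1e-6)
    # Monte-Carlo: mean of sampled hard genotypes converges to the dosage
    draws = np.mean(
        [sample_hard_genotypes(noisy, rng) for _ in range(2000)], axis=0
    )
    assert np.abs(draws - noisy.dosages).max() < 0.08

    with pytest.raises(ValueError):
        add_imputation_noise(panel, calibration=1.5)


def test_effect_variance_flat_when_alpha_zero(rng):
    cfg = SimConfig(n_samples=150, n_snps=3000, alpha=0.0, prop_causal=1.0, seed=9)
    panel = simulate_genotypes(cfg)
    trait = simulate_phenotype(panel, cfg)
    b2 = trait.beta[trait.causal_mask] ** 2
    x = np.log(2 * panel.maf * (1 - panel.maf))[trait.causal_mask]
    slope = np.polyfit(x, np.log(b2), 1)[0]
    assert abs(slope) < 0.12  # ~3.5 MC sd for this size


def test_explained_variance_flat_at_alpha_minus_one(rng):
    # for alpha = -1, 2p(1-p) beta^2 is MAF-independent
    cfg = SimConfig(n_samples=150, n_snps=3000, alpha=-1.0, prop_causal=1.0, seed=10)
    panel = simulate_genotypes(cfg)
    trait = simulate_phenotype(panel, cfg)
    w = 2 * panel.maf * (1 - panel.maf)
    ev = w[trait.causal_mask] * trait.beta[trait.causal_mask] ** 2
    x = np.log(w[trait.causal_mask])
    slope = np.polyfit(x, np.log(ev), 1)[0]
    assert abs(slope) < 0.12


def test_realized_heritability_matches_target():
    cfg = SimConfig(n_samples=300, n_snps=500, h2=0.4, prop_causal=0.1, seed=21)
    panel = simulate_genotypes(cfg)
    r = [
        simulate_phenotype(panel, cfg, seed=500 + i).realized_h2 for i in range(50)
    ]
    assert abs(np.mean(r) - 0.4) < 0.02


def test_zero_h2_is_pure_noise():
    cfg = SimConfig(n_samples=200, n_snps=300, h2=0.0, seed=22)
    panel = simulate_genotypes(cfg)
    trait = simulate_phenotype(panel, cfg)
    assert np.all(trait.beta == 0)
    assert abs(trait.phenotype.mean()) < 1e-10


def test_negative_ld_multiplier_clamped():
    # (1 + tau* LLD) < 0 must clamp to zero variance, not go negative
    w = _effect_variance_weights(
        np.array([0.1, 0.2]), alpha=-0.5, lld=np.array([5.0, 0.0]),
        tau_star=-0.3, t_sim=0.0,
    )
    assert w[0] == 0.0 and w[1] > 0


def test_truncation_freezes_variance_below_threshold(rng):
    maf = np.array([0.01, 0.04, 0.05, 0.2])
    w = _effect_variance_weights(maf, alpha=-0.5, lld=None, tau_star=0.0, t_sim=0.05)
    # below the threshold all variances equal the value at p = T_sim
    assert w[0] == w[1] == w[2]
    assert w[3] != w[0]

    betas = rng.standard_normal(4)
    assert np.array_equal(
        truncate_effects_below_T(betas, maf, 0.0, alpha=-0.5), betas
    )
    scaled = truncate_effects_below_T(betas, maf, 0.05, alpha=-0.5)
    # rescaling reproduces the frozen variance: (scaled/beta)^2 = w(T)/w(p)
    w_plain = (2 * maf * (1 - maf)) ** -0.5
    w_frozen = (2 * 0.05 * 0.95) ** -0.5
    assert np.allclose((scaled[:3] / betas[:3]) ** 2, w_frozen / w_plain[:3])
    assert np.allclose(scaled[3], betas[3])


def test_truncation_attenuates_rare_effect_scaling(rng):
    # with effects frozen below T, a fit over the full MAF range is less
    # negative than a fit restricted to common SNPs
    from alphafreq.evolution import _fit_on_index

    m = 30000
    u = rng.random(m)
    maf = 0.002 * (0.5 / 0.002) ** u
    alpha = -0.5
    w = _effect_variance_weights(maf, alpha, None, 0.0, t_sim=0.05)
    b2 = w * rng.chisquare(1, m)
    logpq = np.log(maf * (1 - maf))
    _, a_full = _fit_on_index(logpq, b2, np.arange(m), (-3, 1))
    common = np.flatnonzero(maf > 0.05)
    _, a_common = _fit_on_index(logpq, b2, common, (-3, 1))
    assert a_common < a_full  # truncated rare end flattens the full-range fit
    assert abs(a_common - alpha) < 0.1
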