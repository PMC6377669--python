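"""Eyre-Walker layer: closed forms, gamma DFE, forward simulation, tau."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.special import gammaln

from alphafreq import (
    Demography,
    EvoModel,
    expected_beta2_derived,
    expected_beta2_maf,
    fit_alpha_to_effects,
    gamma_dfe_stats,
    infer_tau,
    threshold_T,
    wf_forward_simulate,
)

MODEL = EvoModel(tau=0.4, s_bar=1e-3, k=0.25, Ne=10000)


class TestThreshold:
    def test_paper_parameters(self):
        assert threshold_T(MODEL) == pytest.approx(0.00625)

    def test_strong_selection_limit(self):
        m = EvoModel(tau=0.4, s_bar=10.0, k=0.25, Ne=10000)
        assert threshold_T(m) < 1e-5

    def test_linear_in_shape(self):
        m2 = EvoModel(tau=0.4, s_bar=1e-3, k=0.5, Ne=10000)
        assert threshold_T(m2) == pytest.approx(2 * threshold_T(MODEL))

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            EvoModel(tau=0.4, s_bar=-1e-3, k=0.25, Ne=10000)


class TestGammaDFE:
    def test_polygenic_shape(self):
        mean, median, ratio = gamma_dfe_stats(1.0, 1e-3)
        assert mean == pytest.approx(1e-3)
        assert ratio == pytest.approx(1 / np.log(2), rel=1e-6)  # ~1.44

    def test_sparse_shape(self):
        # k = 0.0625: mean/median ~ 6.9e3 ("almost 7000")
        _, _, ratio = gamma_dfe_stats(0.0625, 1e-3)
        assert 6000 < ratio < 7500

    def test_ratio_scale_free(self):
        r1 = gamma_dfe_stats(0.25, 1e-3)[2]
        r2 = gamma_dfe_stats(0.25, 1e-5)[2]
        assert r1 == pytest.approx(r2, rel=1e-9)


def quad_expected_s2tau(p, model):
    """Independent oracle: E(s^2tau | p) as the ratio of integrals with
    P(p|s) ~ [p(1-p)]^-1 exp(-4 Ne s p) and gamma(k, mean s_bar) prior.
    Substituting u = s^k removes the s^(k-1) singularity at the origin."""
    k, tau = model.k, model.tau
    rate = k / model.s_bar
    R = 4 * model.Ne * p + rate

    def num(u):
        return u ** (2 * tau / k) * np.exp(-R * u ** (1 / k))

    def den(u):
        return np.exp(-R * u ** (1 / k))

    a = quad(num, 0, np.inf, epsabs=1e-300, epsrel=1e-10)[0]
    b = quad(den, 0, np.inf, epsabs=1e-300, epsrel=1e-10)[0]
    return a / b


class TestClosedForms:
    @pytest.mark.parametrize("tau", [0.0, 0.4, 1.0])
    @pytest.mark.parametrize("k", [0.125, 0.25])
    def test_derived_form_matches_quadrature(self, tau, k):
        model = EvoModel(tau=tau, s_bar=1e-3, k=k, Ne=10000)
        for p in np.logspace(-4, np.log10(0.2), 9):
            closed = expected_beta2_derived(p, model)
            oracle = quad_expected_s2tau(p, model)
            assert closed == pytest.approx(oracle, rel=0.02)

    def test_tau_zero_is_flat(self):
        m = EvoModel(tau=0.0, s_bar=1e-3, k=0.25, Ne=10000)
        v = expected_beta2_derived(np.array([1e-4, 1e-2, 0.3]), m)
        assert np.ptp(v) < 1e-12
        vm = expected_beta2_maf(np.array([1e-4, 1e-2, 0.45]), m)
        assert np.ptp(vm) < 1e-12

    def test_power_law_above_threshold(self):
        # deep in the power-law regime the ratio approaches (p2/p1)^(-2 tau)
        m = EvoModel(tau=0.4, s_bar=1e-2, k=0.25, Ne=10000)  # T = 6.25e-5
        T = threshold_T(m)
        ratio = expected_beta2_derived(1000 * T, m) / expected_beta2_derived(
            100 * T, m
        )
        assert ratio == pytest.approx(10.0 ** (-2 * m.tau), rel=0.03)

    def test_plateau_below_threshold(self):
        T = threshold_T(MODEL)
        lo = expected_beta2_derived(T / 100, MODEL)
        hi = expected_beta2_derived(T / 10, MODEL)
        assert hi / lo == pytest.approx(1.0, abs=0.1)

    def test_maf_form_matches_folded_quadrature(self):
        # fold the derived-allele kernel over allele labels and compare
        m = MODEL
        for p in [1e-3, 0.01, 0.1, 0.3, 0.5]:
            num = quad_expected_s2tau(p, m) * _site_density(p, m)
            num += quad_expected_s2tau(1 - p, m) * _site_density(1 - p, m)
            den = _site_density(p, m) + _site_density(1 - p, m)
            assert expected_beta2_maf(p, m) == pytest.approx(num / den, rel=1e-6)

    def test_maf_form_continuous_at_half(self):
        a = expected_beta2_maf(0.4999, MODEL)
        b = expected_beta2_maf(0.5, MODEL)
        assert a == pytest.approx(b, rel=1e-3)

    def test_maf_and_derived_forms_share_slope(self):
        # both fall off as p^(-2 tau) above T (levels differ by the folded
        # near-fixation branch)
        p = np.array([0.05, 0.1])
        sd = np.diff(np.log(expected_beta2_derived(p, MODEL)))[0]
        sm = np.diff(np.log(expected_beta2_maf(p, MODEL)))[0]
        assert sd == pytest.approx(sm, rel=0.1)

    def test_maf_form_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            expected_beta2_maf(0.7, MODEL)


def _site_density(p, model):
    """Unnormalized density of derived frequency p under the gamma DFE:
    integral of [p(1-p)]^-1 exp(-4 Ne s p) against the prior, closed form."""
    rate = model.k / model.s_bar
    logv = (
        -np.log(p * (1 - p))
        + gammaln(model.k)
        - model.k * np.log(4 * model.Ne * p + rate)
    )
    return np.exp(logv)


class TestForwardSimulation:
    def test_seeded_determinism(self):
        m = EvoModel(tau=0.4, s_bar=1e-3, k=0.25, Ne=400)
        kw = dict(region_bp=5e4, demography="constant", seed=3, burn_in=400)
        a = wf_forward_simulate(m, **kw)
        b = wf_forward_simulate(m, **kw)
        assert np.array_equal(a.p, b.p) and np.array_equal(a.s, b.s)
        assert np.allclose(a.beta2, m.c * a.s ** (2 * m.tau))

    def test_neutral_sfs_shape(self):
        # near-neutral, constant Ne: the site-frequency spectrum ~ 1/p
        m = EvoModel(tau=0.0, s_bar=1e-8, k=0.25, Ne=500, mu=4e-7)
        smp = wf_forward_simulate(
            m, region_bp=4e5, demography="constant", seed=11,
            linkage=False, burn_in=8 * 500,
        )
        edges = np.array([1 / 1000, 0.005, 0.025, 0.125, 0.625])
        counts, _ = np.histogram(smp.p, bins=edges)
        expected = np.diff(np.log(edges))  # integral of 1/p per bin
        ratio = counts / counts.sum() / (expected / expected.sum())
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0)

    def test_selection_shifts_sfs_rare(self):
        kw = dict(region_bp=3e5, demography="constant", seed=5,
                  linkage=False, burn_in=4000)
        neutral = wf_forward_simulate(
            EvoModel(tau=0.4, s_bar=1e-8, k=0.25, Ne=500, mu=4e-7), **kw
        )
        selected = wf_forward_simulate(
            EvoModel(tau=0.4, s_bar=0.05, k=0.25, Ne=500, mu=4e-7), **kw
        )
        assert np.median(selected.p) <= np.median(neutral.p)
        assert (selected.p > 0.1).mean() < (neutral.p > 0.1).mean()

    def test_linked_simulator_runs_demography(self):
        m = EvoModel(tau=0.4, s_bar=1e-3, k=0.25, Ne=10000, mu=2e-8)
        demo = Demography.european(
            N_ancestral=10000, burn_in=600, N_bottleneck=2000,
            bottleneck_gens=200, N_final=6000, growth_gens=100,
        )
        smp = wf_forward_simulate(
            m, region_bp=2e5, demography=demo, seed=1, rescale=25.0
        )
        assert smp.p.size > 100
        assert np.all((smp.p > 0) & (smp.p < 1))
        assert np.all(smp.s > 0)  # de-rescaled selection coefficients

    def test_rejects_tiny_region(self):
        with pytest.raises(ValueError):
            wf_forward_simulate(MODEL, region_bp=100)


class TestFitAlpha:
    def test_exact_power_law_recovery(self, rng):
        p = rng.uniform(0.01, 0.5, 5000)
        from alphafreq.evolution import SelectedSNPSample

        beta2 = 2.0 * (p * (1 - p)) ** -0.5
        smp = SelectedSNPSample(s=np.ones(5000), p=p, beta2=beta2)
        c, a, _ = fit_alpha_to_effects(smp, maf_min=0.0, n_boot=0)
        assert a == pytest.approx(-0.5, abs=1e-3)
        assert c == pytest.approx(2.0, rel=1e-3)

    def test_bootstrap_se_with_replicates(self, rng):
        from alphafreq.evolution import SelectedSNPSample

        samples = []
        for r in range(8):
            p = rng.uniform(0.01, 0.5, 400)
            beta2 = (p * (1 - p)) ** -0.6 * rng.chisquare(1, 400)
            samples.append(SelectedSNPSample(np.ones(400), p, beta2, r))
        c, a, se = fit_alpha_to_effects(samples, maf_min=0.0, n_boot=50, seed=2)
        assert np.isfinite(se) and se > 0
        assert abs(a + 0.6) < 4 * se + 0.05

    def test_rejects_degenerate(self):
        from alphafreq.evolution import SelectedSNPSample

        smp = SelectedSNPSample(np.ones(200), np.full(200, 0.1), np.ones(200))
        with pytest.raises(ValueError):
            fit_alpha_to_effects(smp, maf_min=0.0)


class TestInferTau:
    def _table(self, se=0.02):
        taus = np.round(np.arange(0.0, 1.01, 0.1), 10)
        return pd.DataFrame(
            {"tau": taus, "alpha_mean": -0.8 * taus, "alpha_se": se}
        )

    def test_delta_inversion(self):
        taus, post, ci = infer_tau((-0.32, 0.01), self._table())
        assert taus[np.argmax(post)] == pytest.approx(0.4, abs=0.05)
        assert ci[0] < 0.4 < ci[1]

    def test_posterior_normalized_under_flat_data(self):
        taus, post, _ = infer_tau((-0.4, 10.0), self._table(se=0.05))
        assert np.trapezoid(post, taus) == pytest.approx(1.0, rel=1e-6)

    def test_requires_full_tau_coverage(self):
        bad = pd.DataFrame(
            {"tau": [0.2, 0.4], "alpha_mean": [-0.1, -0.3], "alpha_se": 0.05}
        )
        with pytest.raises(ValueError):
            infer_tau((-0.3, 0.05), bad)
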