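"""Cross-trait synthesis of alpha estimates.

Inverse-variance-weighted mean, a chi-square heterogeneity test, and the
best-fit dispersion of true alpha across traits (matching the variance of
simulated estimates, given each trait's standard error, to the observed
variance of the estimates).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2

__all__ = ["TraitEstimateSet", "ivw_mean", "heterogeneity_test", "best_fit_sd"]


@dataclass
class TraitEstimateSet:
    trait_ids: Sequence[str]
    alpha_hat: np.ndarray
    se: np.ndarray

    def __post_init__(self):
        self.alpha_hat = np.asarray(self.alpha_hat, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        if len(self.trait_ids) != self.alpha_hat.size or self.alpha_hat.size != self.se.size:
            raise ValueError("trait_ids, alpha_hat and se must have equal length")
        if np.any(self.se <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n(self) -> int:
        return self.alpha_hat.size


def ivw_mean(estimates: TraitEstimateSet) -> Tuple[float, float]:
    """Inverse-variance-weighted mean and its standard error."""
    w = 1.0 / estimates.se**2
    mean = float(np.sum(w * estimates.alpha_hat) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    return mean, se


def heterogeneity_test(
    estimates: TraitEstimateSet, df: Optional[int] = None
) -> Tuple[float, float]:
    """Chi-square test of heterogeneity of true alpha across traits.

    Statistic: sum_i (alpha_i - alpha_cross-trait)^2 / se_i^2, compared to a
    chi-square with n degrees of freedom by default. Because the cross-trait
    mean is estimated from the same data, the classical null is chi-square
    with n-1 df; pass ``df=n-1`` for that convention (the default keeps the
    n-df reference).
    """
    if estimates.n < 2:
        raise ValueError("need at least 2 traits")
    mean, _ = ivw_mean(estimates)
    stat = float(np.sum((estimates.alpha_hat - mean) ** 2 / estimates.se**2))
    if df is None:
        df = estimates.n
    return stat, float(chi2.sf(stat, df))


def best_fit_sd(
    estimates: TraitEstimateSet,
    n_reps: int = 10000,
    n_boot: int = 100,
    seed: int = 0,
) -> Tuple[float, float]:
    """Best-fit sd of true alpha across traits, with a bootstrap se.

    Assumes true alpha_i ~ N(ivw mean, sd^2) and observed estimates add
    N(0, se_i^2) noise; searches the sd >= 0 for which the variance of
    simulated estimate sets best matches the observed variance of the
    estimates (common random numbers keep the objective monotone, so
    bisection applies). The boundary sd = 0 is returned whenever the observed
    variance is below the noise floor.
    """
    if estimates.n < 3:
        raise ValueError("need at least 3 traits")
    rng = np.random.default_rng(seed)

    def _fit(alpha_hat: np.ndarray, se: np.ndarray, z: np.ndarray) -> float:
        obs_var = alpha_hat.var(ddof=1)
        mom = max(0.0, obs_var - np.mean(se**2))

        def sim_var(sd):
            draws = z * np.sqrt(sd**2 + se[None, :] ** 2)
            return draws.var(axis=1, ddof=1).mean()

        if sim_var(0.0) >= obs_var:
            return 0.0
        lo, hi = 0.0, max(2.0 * np.sqrt(mom), 0.05)
        while sim_var(hi) < obs_var and hi < 10.0:
            hi *= 2.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if sim_var(mid) < obs_var:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    z = rng.standard_normal((n_reps, estimates.n))
    sd_hat = _fit(estimates.alpha_hat, estimates.se, z)

    mean, _ = ivw_mean(estimates)
    boots = np.empty(n_boot)
    zb = rng.standard_normal((max(n_reps // 5, 1000), estimates.n))
    for b in range(n_boot):
        sim = mean + rng.standard_normal(estimates.n) * np.sqrt(
            sd_hat**2 + estimates.se**2
        )
        boots[b] = _fit(sim, estimates.se, zb)
    return float(sd_hat), float(boots.std(ddof=1))
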