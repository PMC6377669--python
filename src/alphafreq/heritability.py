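"""Bias-corrected SNP-heritability and MAF partitioning under the alpha model.

With per-normalized-allele effects i.i.d. after the [2p(1-p)]^(alpha/2)
column reweighting, the genetic variance is A * sigma_g_alpha^2 with

    A = sum_j [2 p_j (1 - p_j)]^(1 + alpha)        (times (1 - c*LLD_j)
                                                   for the LD-weighted variant)

so h2 = A s_g2 / (A s_g2 + s_e2). The same [2p(1-p)]^(1+alpha) weight, taken
against an allele-frequency spectrum, gives the fraction of SNP-heritability
contributed by SNPs below any MAF cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Tuple, Union

import numpy as np
from scipy.stats import truncnorm

__all__ = [
    "H2Estimate",
    "FreqSpectrum",
    "compute_A",
    "estimate_h2",
    "h2_fraction_by_maf",
    "propagate_alpha_uncertainty",
]


@dataclass
class H2Estimate:
    h2: float
    A: float
    alpha_used: float
    with_ld_weights: bool
    sigma_g_alpha2: float
    sigma_eps2: float
    boundary: bool = False


@dataclass
class FreqSpectrum:
    """Allele-frequency spectrum: per-SNP MAFs/weights or a continuous density.

    Discrete form: ``maf`` values with ``counts`` (SNP counts or weights).
    Continuous form: a ``density`` callable on (0, 0.5], integrated on a dense
    log-spaced grid.
    """

    maf: Optional[np.ndarray] = None
    counts: Optional[np.ndarray] = None
    density: Optional[Callable[[np.ndarray], np.ndarray]] = None
    support: Tuple[float, float] = (0.0007, 0.5)

    def __post_init__(self):
        if self.maf is not None:
            self.maf = np.asarray(self.maf, dtype=float)
            if np.any(self.maf <= 0) or np.any(self.maf > 0.5):
                raise ValueError("maf must lie in (0, 0.5]")
            if self.counts is None:
                self.counts = np.ones_like(self.maf)
            self.counts = np.asarray(self.counts, dtype=float)
            if np.any(self.counts < 0):
                raise ValueError("counts must be nonnegative")
        elif self.density is None:
            raise ValueError("provide per-SNP maf or a density")

    @classmethod
    def from_bins(cls, low, high, count) -> "FreqSpectrum":
        """Binned counts (TSV style: maf_bin_low, maf_bin_high, count),
        represented at bin midpoints."""
        low = np.asarray(low, dtype=float)
        high = np.asarray(high, dtype=float)
        return cls(maf=(low + high) / 2.0, counts=np.asarray(count, dtype=float))

    @classmethod
    def one_over_p(cls, floor: float = 0.0007) -> "FreqSpectrum":
        """Analytic 1/p spectrum truncated at ``floor`` (neutral-like excess
        of rare variants)."""
        return cls(density=lambda p: 1.0 / p, support=(floor, 0.5))

    def grid(self, n: int = 20001):
        lo, hi = self.support
        p = np.exp(np.linspace(np.log(lo), np.log(hi), n))
        return p, self.density(p)


def compute_A(
    maf: np.ndarray,
    alpha: float,
    lld: Optional[np.ndarray] = None,
    coefficient: float = 0.3,
) -> float:
    """A = sum_j [2 p_j (1-p_j)]^(1+alpha), with the (1 - c*LLD_j) factor for
    the LD-weighted estimator (the squared column weight enters A once)."""
    p = np.asarray(maf, dtype=float)
    w = (2.0 * p * (1.0 - p)) ** (1.0 + alpha)
    if lld is not None:
        w = w * np.clip(1.0 - coefficient * np.asarray(lld, dtype=float), 0.0, None)
    return float(w.sum())


def estimate_h2(
    maf_or_panel,
    remlfit,
    alpha: Union[float, "object"],
    lld: Optional[np.ndarray] = None,
    coefficient: float = 0.3,
    normalizer: float = 1.0,
) -> H2Estimate:
    """h2 = A s_g2 / (A s_g2 + s_e2) from a REML fit at the alpha estimate.

    ``alpha`` may be a float or an AlphaFitResult (its mode is used).
    ``normalizer`` undoes any GRM rescaling recorded at construction.
    A boundary REML fit (sigma_g2 = 0) yields h2 = 0, flagged.
    """
    maf = getattr(maf_or_panel, "maf", maf_or_panel)
    a = getattr(alpha, "alpha_hat", alpha)
    A = compute_A(maf, a, lld=lld, coefficient=coefficient)
    sg2 = remlfit.sigma_g2 * normalizer
    se2 = remlfit.sigma_eps2
    denom = A * sg2 + se2
    h2 = float(A * sg2 / denom) if denom > 0 else 0.0
    return H2Estimate(
        h2=h2,
        A=A,
        alpha_used=float(a),
        with_ld_weights=lld is not None,
        sigma_g_alpha2=sg2,
        sigma_eps2=se2,
        boundary=getattr(remlfit, "boundary", False),
    )


def _fraction_discrete(maf, counts, alpha, maf_cut):
    w = counts * (2.0 * maf * (1.0 - maf)) ** (1.0 + alpha)
    total = w.sum()
    if total <= 0:
        raise ValueError("empty spectrum")
    return float(w[maf <= maf_cut].sum() / total)


def h2_fraction_by_maf(
    alpha: float, spectrum: FreqSpectrum, maf_cut: float
) -> float:
    """Fraction of SNP-heritability from SNPs with MAF <= maf_cut.

    Each SNP contributes heritability proportional to [2p(1-p)]^(1+alpha); the
    fraction is the spectrum-weighted ratio of this weight below the cutoff to
    the total. Continuous spectra are integrated by the trapezoid rule on a
    dense log-spaced grid.
    """
    if not 0.0 < maf_cut <= 0.5:
        raise ValueError("maf_cut must be in (0, 0.5]")
    if spectrum.maf is not None:
        return _fraction_discrete(spectrum.maf, spectrum.counts, alpha, maf_cut)
    lo, hi = spectrum.support
    cut = min(maf_cut, hi)

    def _integral(a, b, n=20001):
        if b <= a:
            return 0.0
        p = np.exp(np.linspace(np.log(a), np.log(b), n))
        w = spectrum.density(p) * (2.0 * p * (1.0 - p)) ** (1.0 + alpha)
        return float(np.trapezoid(w, p))

    below = _integral(lo, cut)
    above = _integral(cut, hi)
    return below / (below + above)


def propagate_alpha_uncertainty(
    alpha_mean: float,
    alpha_sd: float,
    spectrum: FreqSpectrum,
    maf_cut: float,
    n_draws: int = 10000,
    seed: int = 0,
    bounds: Tuple[float, float] = (-2.0, 1.0),
) -> Tuple[float, float]:
    """Monte-Carlo mean and sd of the heritability fraction over
    alpha ~ N(mean, sd^2) truncated to ``bounds``."""
    if alpha_sd < 0:
        raise ValueError("alpha_sd must be nonnegative")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if alpha_sd == 0:
        f = h2_fraction_by_maf(alpha_mean, spectrum, maf_cut)
        return f, 0.0
    rng = np.random.default_rng(seed)
    a_lo, a_hi = (bounds[0] - alpha_mean) / alpha_sd, (bounds[1] - alpha_mean) / alpha_sd
    draws = truncnorm.rvs(
        a_lo, a_hi, loc=alpha_mean, scale=alpha_sd, size=n_draws, random_state=rng
    )
    if spectrum.maf is not None:
        p, c = spectrum.maf, spectrum.counts
        logw = np.log(2.0 * p * (1.0 - p))
        below = p <= maf_cut
        fracs = np.empty(n_draws)
        for i in range(0, n_draws, 512):
            a = draws[i : i + 512]
            w = c[None, :] * np.exp((1.0 + a)[:, None] * logw[None, :])
            fracs[i : i + 512] = w[:, below].sum(axis=1) / w.sum(axis=1)
    else:
        lo, hi = spectrum.support
        cut = min(maf_cut, hi)
        p_lo = np.exp(np.linspace(np.log(lo), np.log(cut), 4001))
        p_hi = np.exp(np.linspace(np.log(cut), np.log(hi), 4001))
        fracs = np.empty(n_draws)
        for i in range(0, n_draws, 512):
            a = (1.0 + draws[i : i + 512])[:, None]
            blw = np.trapezoid(
                spectrum.density(p_lo) * (2 * p_lo * (1 - p_lo)) ** a, p_lo, axis=1
            )
            abv = np.trapezoid(
                spectrum.density(p_hi) * (2 * p_hi * (1 - p_hi)) ** a, p_hi, axis=1
            )
            fracs[i : i + 512] = blw / (blw + abv)
    return float(fracs.mean()), float(fracs.std())
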