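"""Profile likelihood of alpha: grid evaluation, spline mode, credible bands.

For each alpha on a grid the GRM K(alpha) = X~ D_alpha X~^T is built and the
restricted likelihood maximized over the two variance components; the grid is
extended until the mode-to-boundary gap in log profile likelihood reaches 5,
then interpolated with a natural cubic spline. The spline argmax is the
estimate; flat-prior credible intervals come from normalizing exp(logPL) over
the sampled range.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator

from . import heritability as _h2
from .ld import compute_ld_scores, compute_lld
from .reml import GRM, RemlFit, build_grm, reml_fit
from .simdata import GenotypePanel

__all__ = [
    "AlphaFitResult",
    "profile_likelihood",
    "credible_interval",
    "joint_alpha_tau_grid",
    "alpha_common",
    "AlphaModel",
]

DEFAULT_GRID = np.round(np.arange(-1.0, 0.0 + 1e-9, 0.05), 10)
GAP_RULE = 5.0  # required log-PL drop from mode to each grid boundary
FLAT_RANGE = 0.5  # curves flatter than this carry no information on alpha
EXTENSION_CAP = (-2.0, 1.0)


@dataclass
class AlphaFitResult:
    """Profile-likelihood curve for alpha with mode and credible interval."""

    grid_alpha: np.ndarray
    loglik: np.ndarray
    alpha_hat: float
    ci95: Tuple[float, float]
    se: float
    tau_star: float
    per_point_fits: List[RemlFit] = field(default_factory=list)
    flat: bool = False

    @property
    def spline(self) -> CubicSpline:
        return CubicSpline(self.grid_alpha, self.loglik, bc_type="natural")

    def posterior(self, n_dense: Optional[int] = None):
        """Flat-prior posterior density of alpha on a dense grid."""
        a, b = self.grid_alpha[0], self.grid_alpha[-1]
        if n_dense is None:
            n_dense = max(int(round((b - a) / 1e-4)) + 1, 201)
        x = np.linspace(a, b, n_dense)
        ll = self.spline(x)
        dens = np.exp(ll - ll.max())
        z = np.trapezoid(dens, x)
        return x, dens / z


def _fit_at_alpha(
    panel_batches,
    y_batches,
    cov_batches,
    lld_batches,
    alpha: float,
    tau_star: float,
    dtype=np.float64,
) -> Tuple[float, List[RemlFit]]:
    """Sum of per-batch restricted logliks at one alpha (the batching device
    trades a small information loss for linear memory in the sample size)."""
    ll = 0.0
    fits = []
    for panel, y, cov, lld in zip(panel_batches, y_batches, cov_batches, lld_batches):
        grm = build_grm(panel, alpha, lld=lld, tau_star=tau_star, dtype=dtype)
        fit = reml_fit(grm, y, cov)
        ll += fit.loglik_restricted
        fits.append(fit)
    return ll, fits


def _split_batches(panel, y, covariates, lld, n_batches):
    if n_batches <= 1:
        return [panel], [y], [covariates], [lld]
    n = panel.n_samples
    idx = np.array_split(np.arange(n), n_batches)
    panels, ys, covs, llds = [], [], [], []
    for ix in idx:
        panels.append(
            GenotypePanel(
                dosages=panel.dosages[ix],
                maf=panel.maf,
                positions=panel.positions,
                snp_ids=panel.snp_ids,
            )
        )
        ys.append(np.asarray(y)[ix])
        covs.append(None if covariates is None else np.asarray(covariates)[ix])
        llds.append(lld)
    return panels, ys, covs, llds


def _mode_from_spline(grid, ll, step=1e-4):
    cs = CubicSpline(grid, ll, bc_type="natural")
    x = np.linspace(grid[0], grid[-1], max(int((grid[-1] - grid[0]) / step) + 1, 201))
    v = cs(x)
    return float(x[np.argmax(v)]), cs


def credible_interval(
    result: AlphaFitResult, mass: float = 0.95, method: str = "eti"
) -> Tuple[float, float]:
    """Flat-prior credible interval from the spline profile likelihood.

    Equal-tailed by default ("eti"); "hpd" returns the highest-posterior-
    density interval. Normalization is over the sampled grid range only.
    """
    if result.flat:
        return (float(result.grid_alpha[0]), float(result.grid_alpha[-1]))
    x, dens = result.posterior()
    dx = x[1] - x[0]
    if method == "eti":
        cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * dx)])
        cdf /= cdf[-1]
        lo = float(np.interp((1 - mass) / 2, cdf, x))
        hi = float(np.interp(1 - (1 - mass) / 2, cdf, x))
        return lo, hi
    if method == "hpd":
        order = np.argsort(dens)[::-1]
        csum = np.cumsum(dens[order]) * dx
        cutoff = dens[order[np.searchsorted(csum, mass)]]
        inside = x[dens >= cutoff]
        return float(inside.min()), float(inside.max())
    raise ValueError("method must be 'eti' or 'hpd'")


def _posterior_sd(result: AlphaFitResult) -> float:
    x, dens = result.posterior()
    mean = np.trapezoid(x * dens, x)
    var = np.trapezoid((x - mean) ** 2 * dens, x)
    return float(np.sqrt(max(var, 0.0)))


def profile_likelihood(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    lld: Optional[np.ndarray] = None,
    tau_star: float = -0.3,
    grid: Optional[Sequence[float]] = None,
    n_batches: int = 1,
    extend: bool = True,
    cap: Tuple[float, float] = EXTENSION_CAP,
    dtype=np.float64,
) -> AlphaFitResult:
    """Profile likelihood of alpha with grid extension and spline mode.

    When ``lld`` is None no LD weights are used (the "noLD" estimator).
    ``n_batches`` > 1 splits individuals into disjoint batches and sums the
    per-batch restricted log-likelihoods.
    """
    grid = np.asarray(DEFAULT_GRID if grid is None else grid, dtype=float)
    step = grid[1] - grid[0] if grid.size > 1 else 0.05
    batches = _split_batches(panel, phenotype, covariates, lld, n_batches)

    values = {}
    fits = {}
    for a in grid:
        values[round(a, 10)], fits[round(a, 10)] = _fit_at_alpha(
            *batches, alpha=a, tau_star=tau_star, dtype=dtype
        )

    def _sorted_items():
        ks = sorted(values)
        return np.array(ks), np.array([values[k] for k in ks])

    if extend:
        for direction in (+1, -1):
            while True:
                ks, ll = _sorted_items()
                gap = ll.max() - (ll[-1] if direction > 0 else ll[0])
                if gap >= GAP_RULE:
                    break
                nxt = round((ks[-1] if direction > 0 else ks[0]) + direction * step, 10)
                if nxt > cap[1] + 1e-9 or nxt < cap[0] - 1e-9:
                    break
                values[nxt], fits[nxt] = _fit_at_alpha(
                    *batches, alpha=nxt, tau_star=tau_star, dtype=dtype
                )

    ks, ll = _sorted_items()
    flat = (ll.max() - ll.min()) < FLAT_RANGE
    if flat:
        result = AlphaFitResult(
            grid_alpha=ks,
            loglik=ll,
            alpha_hat=np.nan,
            ci95=(float(ks[0]), float(ks[-1])),
            se=np.nan,
            tau_star=tau_star if lld is not None else 0.0,
            per_point_fits=[fits[k] for k in ks],
            flat=True,
        )
        return result
    mode, _ = _mode_from_spline(ks, ll)
    result = AlphaFitResult(
        grid_alpha=ks,
        loglik=ll,
        alpha_hat=mode,
        ci95=(np.nan, np.nan),
        se=np.nan,
        tau_star=tau_star if lld is not None else 0.0,
        per_point_fits=[fits[k] for k in ks],
    )
    result.ci95 = credible_interval(result)
    result.se = _posterior_sd(result)
    return result


def joint_alpha_tau_grid(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    lld: Optional[np.ndarray] = None,
    alpha_grid: Optional[Sequence[float]] = None,
    tau_grid: Sequence[float] = (-0.60, -0.45, -0.30, -0.15, 0.00),
    n_batches: int = 1,
):
    """2-D restricted log-likelihood surface over (alpha, tau*).

    Returns (loglik matrix [n_alpha, n_tau], alpha_hat, tau_star_hat, and the
    marginal AlphaFitResult at the best tau*). The tau* = 0 column equals the
    unweighted analysis by construction.
    """
    if lld is None:
        raise ValueError("joint fitting requires an LLD vector")
    alpha_grid = np.asarray(DEFAULT_GRID if alpha_grid is None else alpha_grid)
    tau_grid = np.asarray(tau_grid, dtype=float)
    batches = _split_batches(panel, phenotype, covariates, lld, n_batches)
    surface = np.empty((alpha_grid.size, tau_grid.size))
    for jt, t in enumerate(tau_grid):
        use_lld = None if t == 0.0 else lld
        bt = batches if t != 0.0 else _split_batches(
            panel, phenotype, covariates, None, n_batches
        )
        for ja, a in enumerate(alpha_grid):
            surface[ja, jt], _ = _fit_at_alpha(*bt, alpha=a, tau_star=t)
    ja, jt = np.unravel_index(np.argmax(surface), surface.shape)
    best_tau = float(tau_grid[jt])
    marginal = profile_likelihood(
        panel,
        phenotype,
        covariates,
        lld=None if best_tau == 0.0 else lld,
        tau_star=best_tau,
        grid=alpha_grid,
        n_batches=n_batches,
        extend=False,
    )
    return surface, float(alpha_grid[ja]), best_tau, marginal


def alpha_common(
    panel: GenotypePanel,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    lld: Optional[np.ndarray] = None,
    maf_min: float = 0.05,
    full_result: Optional[AlphaFitResult] = None,
    **kwargs,
):
    """Re-estimate alpha using only SNPs with MAF > maf_min.

    Returns (common_result, diff, se_diff) where diff = alpha_common - alpha
    of the full panel and se_diff conservatively sums the two posterior
    variances (the two curves share data and are positively correlated, so
    this overstates the spread).
    """
    keep = panel.maf > maf_min
    if keep.sum() < 2:
        raise ValueError("MAF filter leaves too few SNPs")
    sub = panel.subset_snps(keep)
    sub_lld = None if lld is None else np.asarray(lld)[keep]
    common = profile_likelihood(sub, phenotype, covariates, lld=sub_lld, **kwargs)
    if full_result is None:
        full_result = profile_likelihood(
            panel, phenotype, covariates, lld=lld, **kwargs
        )
    diff = common.alpha_hat - full_result.alpha_hat
    se_diff = float(np.sqrt(np.nansum([common.se**2, full_result.se**2])))
    return common, diff, se_diff


class AlphaModel(BaseEstimator):
    """Estimator of the MAF-dependence exponent alpha of SNP effect sizes.

    Fits the variance-component model y ~ N(0, sigma_g2 K(alpha) + sigma_e2 I)
    over a grid of alpha by REML, interpolates the profile likelihood with a
    natural cubic spline and reports the mode, a flat-prior credible interval
    and a bias-corrected SNP-heritability.

    Parameters
    ----------
    grid_start, grid_stop, grid_step : alpha grid (extended automatically
        until the mode-to-boundary log-likelihood gap reaches 5).
    ld_weights : include LD-dependent SNP weights (1 + tau_star * LLD).
    tau_star : LD-architecture coefficient (default -0.3).
    window_kb, n_maf_bins : LD-score window and MAF bins for the LLD
        covariate when it is computed internally.
    maf_min : drop SNPs at or below this MAF before fitting.
    n_batches : split individuals into batches and sum restricted logliks.

    Attributes
    ----------
    alpha_hat_, se_, ci95_ : point estimate and flat-prior uncertainty.
    grid_alpha_, loglik_ : sampled profile-likelihood curve.
    h2_, sigma_g_alpha2_, sigma_eps2_ : heritability pieces at alpha_hat_.
    result_ : the full AlphaFitResult.
    """

    def __init__(
        self,
        grid_start: float = -1.0,
        grid_stop: float = 0.0,
        grid_step: float = 0.05,
        ld_weights: bool = True,
        tau_star: float = -0.3,
        window_kb: float = 1000.0,
        n_maf_bins: int = 20,
        maf_min: float = 0.0,
        n_batches: int = 1,
        extend: bool = True,
    ) -> None:
        self.grid_start = grid_start
        self.grid_stop = grid_stop
        self.grid_step = grid_step
        self.ld_weights = ld_weights
        self.tau_star = tau_star
        self.window_kb = window_kb
        self.n_maf_bins = n_maf_bins
        self.maf_min = maf_min
        self.n_batches = n_batches
        self.extend = extend

    def _grid(self):
        return np.round(
            np.arange(self.grid_start, self.grid_stop + 1e-9, self.grid_step), 10
        )

    def fit(
        self,
        X,
        y,
        maf: Optional[np.ndarray] = None,
        positions: Optional[np.ndarray] = None,
        covariates: Optional[np.ndarray] = None,
        lld: Optional[np.ndarray] = None,
    ) -> "AlphaModel":
        """Fit the profile likelihood of alpha on dosages X and phenotype y.

        X may be a GenotypePanel or an (N, M) dosage array; with a raw array,
        MAF is computed from column means and positions default to a 1 kb
        ladder.
        """
        if isinstance(X, GenotypePanel):
            panel = X
        else:
            X = np.asarray(X, dtype=float)
            if maf is None:
                maf = np.minimum(X.mean(axis=0) / 2.0, 1.0 - X.mean(axis=0) / 2.0)
            if positions is None:
                positions = np.arange(1, X.shape[1] + 1) * 1000
            panel = GenotypePanel(dosages=X, maf=maf, positions=positions)
        y = np.asarray(y, dtype=float)
        if panel.n_samples != y.shape[0]:
            raise ValueError("X and y have incompatible shapes")
        if self.maf_min > 0:
            keep = panel.maf > self.maf_min
            panel = panel.subset_snps(keep)
            if lld is not None:
                lld = np.asarray(lld)[keep]
        if self.ld_weights and lld is None:
            scores = compute_ld_scores(panel, window_kb=self.window_kb)
            lld = compute_lld(scores, panel.maf, n_bins=self.n_maf_bins).lld
        if not self.ld_weights:
            lld = None
        self.lld_ = lld

        result = profile_likelihood(
            panel,
            y,
            covariates=covariates,
            lld=lld,
            tau_star=self.tau_star,
            grid=self._grid(),
            n_batches=self.n_batches,
            extend=self.extend,
        )
        self.result_ = result
        self.grid_alpha_ = result.grid_alpha
        self.loglik_ = result.loglik
        self.alpha_hat_ = result.alpha_hat
        self.ci95_ = result.ci95
        self.se_ = result.se
        self.flat_ = result.flat

        if not result.flat:
            grm = build_grm(panel, result.alpha_hat, lld=lld, tau_star=self.tau_star)
            fit = reml_fit(grm, y, covariates)
            est = _h2.estimate_h2(
                panel.maf, fit, result.alpha_hat, lld=lld,
                coefficient=-self.tau_star if lld is not None else 0.3,
                normalizer=grm.normalizer,
            )
            self.h2_ = est.h2
            self.sigma_g_alpha2_ = est.sigma_g_alpha2
            self.sigma_eps2_ = est.sigma_eps2
        else:
            self.h2_ = np.nan
            self.sigma_g_alpha2_ = np.nan
            self.sigma_eps2_ = np.nan
        return self
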