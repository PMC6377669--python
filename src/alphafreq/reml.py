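"""Restricted maximum likelihood for the two-component mixed model.

The model is y ~ N(C b, sigma_g2 * K + sigma_e2 * I) with fixed-effect
covariates C (always including an intercept) and a genetic relationship
matrix K = X~ D_alpha X~^T built from mean-centered, MAF- and LD-weighted
dosages. The restricted likelihood is the Gaussian likelihood of A^T y where
A is an orthonormal basis of the orthogonal complement of the column space
of C; after one eigendecomposition of A^T K A the fit reduces to a 1-D
search over the variance ratio with the total variance profiled out in
closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import eigh, qr
from scipy.optimize import minimize_scalar

from .simdata import GenotypePanel

__all__ = ["GRM", "RemlFit", "build_grm", "reml_fit", "restricted_loglik"]

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class GRM:
    """Genetic relationship matrix with its construction record."""

    matrix: np.ndarray
    normalizer: float
    alpha_used: float
    tau_star_used: float
    n_snps_used: int


@dataclass
class RemlFit:
    sigma_g2: float
    sigma_eps2: float
    loglik_restricted: float
    converged: bool
    n_covariates: int
    boundary: bool = False
    identifiable: bool = True


def snp_weights(
    maf: np.ndarray,
    alpha: float,
    lld: Optional[np.ndarray] = None,
    tau_star: float = -0.3,
) -> np.ndarray:
    """Per-SNP effect-variance weights [2p(1-p)]^alpha * max(0, 1 + tau* LLD)."""
    p = np.asarray(maf, dtype=float)
    w = (2.0 * p * (1.0 - p)) ** alpha
    if lld is not None:
        w = w * np.clip(1.0 + tau_star * np.asarray(lld, dtype=float), 0.0, None)
    return w


def build_grm(
    panel: GenotypePanel,
    alpha: float,
    lld: Optional[np.ndarray] = None,
    tau_star: float = -0.3,
    normalize: bool = False,
    dtype=np.float64,
) -> GRM:
    """K = X~ D_alpha X~^T with mean-centered, optionally LD-weighted columns.

    Zero-variance SNPs are dropped (with a logged count). When ``normalize``
    is set, K is rescaled to trace(K)/N = 1 and the factor recorded; any
    positive rescaling of K only rescales sigma_g2 and leaves the profile
    likelihood shape in alpha unchanged.
    """
    if np.any(panel.maf <= 0) or np.any(panel.maf > 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    X = panel.dosages
    sd = X.std(axis=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        logger.info("build_grm: dropped %d zero-variance SNPs", dropped)
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    w = snp_weights(
        panel.maf[keep],
        alpha,
        None if lld is None else np.asarray(lld)[keep],
        tau_star,
    )
    Xw = (Xc * np.sqrt(w)[None, :]).astype(dtype, copy=False)
    K = (Xw @ Xw.T).astype(np.float64, copy=False)
    normalizer = 1.0
    if normalize:
        tr = np.trace(K) / K.shape[0]
        if tr > 0:
            K /= tr
            normalizer = 1.0 / tr
    return GRM(
        matrix=K,
        normalizer=normalizer,
        alpha_used=alpha,
        tau_star_used=0.0 if lld is None else tau_star,
        n_snps_used=int(keep.sum()),
    )


def _complement_basis(n: int, covariates: Optional[np.ndarray]) -> np.ndarray:
    """Orthonormal basis of the complement of span(intercept, covariates)."""
    c = np.ones((n, 1))
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        c = np.column_stack([c, covariates])
    q, r, _ = qr(c, mode="full", pivoting=True)
    d = np.abs(np.diag(r))
    rank = int(np.sum(d > 1e-10 * max(d.max(), 1)))
    if rank < c.shape[1]:
        logger.warning("covariate matrix is rank deficient (%d < %d)", rank, c.shape[1])
    return q[:, rank:]


def _spectral_reduction(K, y, covariates):
    n = K.shape[0]
    A = _complement_basis(n, covariates)
    Kr = A.T @ K @ A
    yr = A.T @ np.asarray(y, dtype=float)
    lam, U = eigh(Kr)
    lam = np.clip(lam, 0.0, None)
    u = U.T @ yr
    q = n - A.shape[1]
    return lam, u, q


def _loglik_gamma(gamma: float, lam: np.ndarray, u: np.ndarray):
    """Restricted loglik maximized over total variance at ratio gamma."""
    d = gamma * lam + 1.0
    nr = lam.size
    se2 = float(np.mean(u * u / d))
    if se2 <= 0:
        return -np.inf, 0.0
    ll = -0.5 * (np.log(d).sum() + nr * np.log(se2) + nr + nr * _LOG2PI)
    return ll, se2


def restricted_loglik(
    grm: GRM,
    y: np.ndarray,
    covariates: Optional[np.ndarray],
    sigma_g2: float,
    sigma_eps2: float,
) -> float:
    """Restricted log-likelihood at fixed variance components."""
    lam, u, _ = _spectral_reduction(grm.matrix, y, covariates)
    d = sigma_g2 * lam + sigma_eps2
    return float(-0.5 * (np.log(d).sum() + np.sum(u * u / d) + lam.size * _LOG2PI))


def reml_fit(
    grm: GRM,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    ratio_bounds: tuple = (1e-6, 1e6),
    tol: float = 1e-10,
) -> RemlFit:
    """Maximize the restricted likelihood over (sigma_g2, sigma_eps2).

    One eigendecomposition of the covariate-projected K, then Brent search on
    log(sigma_g2 / sigma_eps2) with the total variance profiled out in closed
    form. Boundary estimates (sigma_g2 = 0) are allowed and flagged.
    """
    y = np.asarray(phenotype, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype must be finite")
    lam, u, n_cov = _spectral_reduction(grm.matrix, y, covariates)
    if lam.size < 2:
        raise ValueError("need at least 2 residual degrees of freedom")

    identifiable = (lam.max() - lam.min()) > 1e-10 * max(lam.max(), 1.0)

    lo, hi = np.log(ratio_bounds[0]), np.log(ratio_bounds[1])
    res = minimize_scalar(
        lambda t: -_loglik_gamma(np.exp(t), lam, u)[0],
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-9},
    )
    gamma = float(np.exp(res.x))
    ll, se2 = _loglik_gamma(gamma, lam, u)

    # compare against the sigma_g2 = 0 boundary
    ll0, se20 = _loglik_gamma(0.0, lam, u)
    boundary = False
    if ll0 >= ll - tol or gamma <= ratio_bounds[0] * (1 + 1e-6):
        if ll0 >= ll:
            gamma, ll, se2 = 0.0, ll0, se20
            boundary = True
        elif gamma <= ratio_bounds[0] * (1 + 1e-6):
            boundary = True
    return RemlFit(
        sigma_g2=gamma * se2,
        sigma_eps2=se2,
        loglik_restricted=float(ll),
        converged=bool(res.success),
        n_covariates=n_cov,
        boundary=boundary,
        identifiable=bool(identifiable),
    )
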