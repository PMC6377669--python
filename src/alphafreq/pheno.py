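"""Phenotype preprocessing: outlier removal, covariate regression, rank-INT.

The pipeline order is fixed: (1) remove values 4 or more sd from the mean,
(2) regress out fixed-effect covariates by ordinary least squares, (3) map
residual ranks through the standard normal quantile function (Blom offset).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "remove_outliers",
    "regress_out_covariates",
    "rank_int",
    "preprocess_phenotype",
]


def remove_outliers(values: np.ndarray, n_sd: float = 4.0) -> np.ndarray:
    """Boolean mask keeping values strictly within n_sd sample sd of the mean.

    Single pass (mean and sd computed once on the full input). Zero-variance
    input keeps everything.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values")
    sd = values.std()
    if sd == 0 or not np.isfinite(n_sd):
        return np.ones(values.size, dtype=bool)
    return np.abs(values - values.mean()) < n_sd * sd


def regress_out_covariates(
    values: np.ndarray, covariate_matrix: Optional[np.ndarray] = None
) -> np.ndarray:
    """OLS residuals after an intercept and the given covariates.

    Collinear columns are handled by the least-squares pseudoinverse (the
    residuals are unaffected by which of the collinear columns gets weight).
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    C = np.ones((n, 1))
    if covariate_matrix is not None:
        cov = np.asarray(covariate_matrix, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match values")
        C = np.column_stack([C, cov])
    coef, *_ = np.linalg.lstsq(C, y, rcond=None)
    return y - C @ coef


def rank_int(values: np.ndarray, offset: float = 0.375) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset c = 3/8.

    Ties receive the mean rank; all-equal input maps to zeros. The transform
    is invariant to any strictly monotone transformation of the input.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("need at least 2 values")
    if np.all(values == values[0]):
        return np.zeros(n)
    ranks = rankdata(values, method="average")
    return norm.ppf((ranks - offset) / (n - 2 * offset + 1))


@dataclass
class PhenoResult:
    processed: np.ndarray
    kept: np.ndarray  # boolean mask into the input
    n_excluded: int


def preprocess_phenotype(
    values: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    n_sd: float = 4.0,
) -> PhenoResult:
    """Full pipeline: outlier removal -> covariate regression -> rank-INT."""
    values = np.asarray(values, dtype=float)
    kept = remove_outliers(values, n_sd=n_sd)
    cov = None if covariates is None else np.asarray(covariates)[kept]
    resid = regress_out_covariates(values[kept], cov)
    return PhenoResult(processed=rank_int(resid), kept=kept, n_excluded=int((~kept).sum()))
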