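"""LD scores and the MAF-stratified level-of-LD (LLD) covariate.

The LD score of SNP j is the sum of finite-sample-adjusted squared Pearson
correlations with every SNP within a physical window (self included). LLD is
the rank-based inverse normal transform of the LD score, computed separately
within MAF-quantile bins so that it is independent of MAF by construction.
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
from scipy.stats import norm, rankdata

from .simdata import GenotypePanel

__all__ = ["LDProfile", "compute_ld_scores", "compute_lld", "apply_ld_weights"]


@dataclass
class LDProfile:
    ld_score: np.ndarray
    lld: np.ndarray
    maf_bin: np.ndarray
    window_kb: float


def compute_ld_scores(
    panel: GenotypePanel, window_kb: float = 1000.0, block: int = 512
) -> np.ndarray:
    """Windowed LD scores with the finite-sample r^2 adjustment.

    ld_score_j = sum over k with |pos_k - pos_j| <= window of
    r2_adj(j, k), where r2_adj = r2 - (1 - r2) / (N - 2) debiases the
    small-sample inflation of squared correlations. The self term contributes
    exactly 1. Zero-variance columns get a score of 1 (self only).
    """
    X = panel.dosages
    pos = np.asarray(panel.positions, dtype=np.int64)
    n, m = X.shape
    if n < 3:
        raise ValueError("need at least 3 samples for adjusted r^2")
    if not np.all(np.diff(pos) >= 0):
        raise ValueError("positions must be sorted")
    sd = X.std(axis=0)
    ok = sd > 0
    Z = np.zeros_like(X)
    Z[:, ok] = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]

    win = window_kb * 1000.0
    scores = np.zeros(m)
    for a in range(0, m, block):
        b = min(a + block, m)
        lo = np.searchsorted(pos, pos[a] - win, side="left")
        hi = np.searchsorted(pos, pos[b - 1] + win, side="right")
        r = Z[:, a:b].T @ Z[:, lo:hi] / n
        r2 = r * r
        r2adj = r2 - (1.0 - r2) / (n - 2)
        inside = (
            np.abs(pos[lo:hi][None, :] - pos[a:b][:, None]) <= win
        )
        valid = ok[a:b][:, None] & ok[lo:hi][None, :] & inside
        scores[a:b] = np.where(valid, r2adj, 0.0).sum(axis=1)
    scores[~ok] = 1.0  # self term only
    return scores


def _blom_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset), standardized."""
    n = values.size
    ranks = rankdata(values, method="average")
    q = norm.ppf((ranks - 0.375) / (n + 0.25))
    sd = q.std()
    if sd == 0:
        return np.zeros(n)
    return (q - q.mean()) / sd


def compute_lld(
    ld_score: np.ndarray,
    maf: np.ndarray,
    n_bins: int = 20,
    window_kb: float = np.nan,
) -> LDProfile:
    """Rank-based inverse normal transform of LD scores within MAF bins.

    SNPs are assigned to MAF-quantile bins; within each bin the LD scores are
    rank-transformed through the standard normal quantile function and
    standardized to mean 0 and variance 1. Bins with fewer than two SNPs (or
    with fully tied scores) get LLD = 0.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ld_score = np.asarray(ld_score, dtype=float)
    maf = np.asarray(maf, dtype=float)
    edges = np.unique(np.quantile(maf, np.linspace(0, 1, n_bins + 1)))
    maf_bin = np.clip(np.searchsorted(edges, maf, side="right") - 1, 0, len(edges) - 2)
    lld = np.zeros_like(ld_score)
    for b in np.unique(maf_bin):
        idx = np.flatnonzero(maf_bin == b)
        if idx.size < 2:
            continue
        lld[idx] = _blom_scores(ld_score[idx])
    return LDProfile(ld_score=ld_score, lld=lld, maf_bin=maf_bin, window_kb=window_kb)


def apply_ld_weights(
    X: np.ndarray, lld: np.ndarray, coefficient: float = 0.3
) -> np.ndarray:
    """Scale dosage columns by sqrt(max(0, 1 - coefficient * LLD_j)).

    High-LD SNPs (LLD > 0) are down-weighted so that, under an LD-dependent
    architecture where their causal effects are smaller, the reweighted
    effects are i.i.d. given MAF. The multiplier is clamped at zero before
    the square root.
    """
    w = np.clip(1.0 - coefficient * np.asarray(lld, dtype=float), 0.0, None)
    return np.asarray(X, dtype=float) * np.sqrt(w)[None, :]
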