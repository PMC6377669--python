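"""Eyre-Walker coupling, gamma DFE, and Wright-Fisher forward simulation.

The Eyre-Walker model couples a SNP's squared trait effect to its selection
coefficient as E(beta^2 | s) = c * s^(2*tau). With a gamma distribution of
fitness effects (mean s_bar, shape k) and the diffusion frequency kernel
P(p|s) ~ [p(1-p)]^-1 exp(-4*Ne*s*p), the MAF-dependence of trait effects has
a closed form with a drift threshold T = k / (4*Ne*s_bar): below T effects
plateau, above T they fall off as p^(-2*tau), so the alpha model holds with
alpha ~ -2*tau in the no-LD constant-size limit. Forward simulation (with
linkage and demography) lets the same quantity be measured under realistic
conditions, where the best-fit alpha is substantially less negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

__all__ = [
    "EvoModel",
    "SelectedSNPSample",
    "Demography",
    "threshold_T",
    "expected_beta2_derived",
    "expected_beta2_maf",
    "gamma_dfe_stats",
    "wf_forward_simulate",
    "fit_alpha_to_effects",
    "infer_tau",
]


@dataclass
class EvoModel:
    """Eyre-Walker coupling plus gamma-DFE parameters.

    tau : coupling exponent, |beta| ~ s^tau (tau = 0 decouples trait from
        fitness); s_bar, k : mean and shape of the gamma DFE of new
        mutations; Ne : effective population size; c : proportionality
        constant of E(beta^2|s) (units of beta^2 are arbitrary); sigma_ew2 :
        Eyre-Walker noise variance (affects single draws, not E(beta^2|s);
        default 0); mu : per-bp per-generation mutation rate.
    """

    tau: float = 0.4
    s_bar: float = 1e-3
    k: float = 0.25
    Ne: int = 10000
    c: float = 1.0
    sigma_ew2: float = 0.0
    mu: float = 2e-8

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.s_bar <= 0 or self.k <= 0 or self.Ne <= 0:
            raise ValueError("s_bar, k and Ne must be positive")

    @property
    def T(self) -> float:
        return self.k / (4.0 * self.Ne * self.s_bar)


@dataclass
class SelectedSNPSample:
    """Segregating sites from one simulation replicate.

    s : selection coefficients (unrescaled units); p : derived allele
    frequencies in (0, 1); beta2 = c * s^(2*tau) exactly.
    """

    s: np.ndarray
    p: np.ndarray
    beta2: np.ndarray
    replicate_id: int = 0


def threshold_T(model: EvoModel) -> float:
    """Drift threshold T = k / (4 Ne s_bar): the highest frequency at which
    even strongly selected SNPs are still dominated by drift."""
    return model.T


def expected_beta2_derived(p, model: EvoModel):
    """Closed-form E(beta^2 | derived frequency p) under the gamma DFE:

    c * Gamma(2 tau + k)/Gamma(k) * (4 Ne)^(-2 tau) * (p + T)^(-2 tau).

    Constant for p << T; falls off as p^(-2 tau) for p >> T.
    """
    p = np.asarray(p, dtype=float)
    t2 = 2.0 * model.tau
    pref = model.c * np.exp(gammaln(t2 + model.k) - gammaln(model.k))
    return pref * (4.0 * model.Ne) ** (-t2) * (p + model.T) ** (-t2)


def expected_beta2_maf(p, model: EvoModel):
    """E(beta^2 | MAF p): the derived-allele form folded over allele labels,

    c * G(2tau+k)/G(k) * (4Ne)^(-2tau) *
        [(p+T)^(-2tau-k) + (1-p+T)^(-2tau-k)] / [(p+T)^(-k) + (1-p+T)^(-k)]

    which follows exactly from mixing the minor- and major-derived branches
    of the frequency kernel. Continuous at p = 0.5 and constant when tau = 0.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 0.5):
        raise ValueError("MAF must lie in (0, 0.5]")
    t2 = 2.0 * model.tau
    T = model.T
    pref = model.c * np.exp(gammaln(t2 + model.k) - gammaln(model.k))
    num = (p + T) ** (-t2 - model.k) + (1.0 - p + T) ** (-t2 - model.k)
    den = (p + T) ** (-model.k) + (1.0 - p + T) ** (-model.k)
    return pref * (4.0 * model.Ne) ** (-t2) * num / den


def gamma_dfe_stats(k: float, s_bar: float) -> Tuple[float, float, float]:
    """(mean, median, mean/median) of the gamma DFE.

    The ratio depends only on the shape k (scale family): ~1.44 at k = 1,
    ~7e3 at k = 0.0625 — small k means extremely sparse fitness effects.
    """
    if k <= 0 or s_bar <= 0:
        raise ValueError("k and s_bar must be positive")
    median = float(gamma_dist.ppf(0.5, k, scale=s_bar / k))
    return s_bar, median, s_bar / median


# ---------------------------------------------------------------------------
# demography


@dataclass
class Demography:
    """Per-epoch diploid population sizes.

    epochs : list of (N, generations); the last epoch may grow exponentially
    from the previous size to N over its duration when ``grow_last`` is set.
    """

    epochs: List[Tuple[int, int]]
    grow_last: bool = False

    @classmethod
    def constant(cls, Ne: int, generations: Optional[int] = None) -> "Demography":
        return cls(epochs=[(Ne, generations if generations else 10 * Ne)])

    @classmethod
    def european(
        cls,
        N_ancestral: int = 10000,
        burn_in: int = 3880,
        N_bottleneck: int = 2000,
        bottleneck_gens: int = 1000,
        N_final: int = 50000,
        growth_gens: int = 900,
    ) -> "Demography":
        """Three-epoch out-of-Africa-style European model: ancestral size with
        the standard burn-in, a bottleneck, then exponential growth."""
        return cls(
            epochs=[
                (N_ancestral, burn_in),
                (N_bottleneck, bottleneck_gens),
                (N_final, growth_gens),
            ],
            grow_last=True,
        )

    def sizes(self, rescale: float = 1.0) -> np.ndarray:
        """Per-generation diploid N, with lambda-rescaling (N/lambda, time/lambda)."""
        out = []
        prev = None
        for i, (N, gens) in enumerate(self.epochs):
            n_sc = max(int(round(N / rescale)), 2)
            g_sc = max(int(round(gens / rescale)), 1)
            if self.grow_last and i == len(self.epochs) - 1 and prev is not None:
                rate = np.log(n_sc / prev) / g_sc
                out.append(np.round(prev * np.exp(rate * np.arange(1, g_sc + 1))))
            else:
                out.append(np.full(g_sc, n_sc))
            prev = int(out[-1][-1])
        return np.concatenate(out).astype(int)


# ---------------------------------------------------------------------------
# forward simulation


def _inject_mutations(rng, H, s_eff, pos, n_sites, new_count, L, k, scale):
    """Append new mutations as single-copy columns; returns new n_sites."""
    cap = H.shape[1]
    if n_sites + new_count > cap:
        new_cap = max(2 * cap, n_sites + new_count)
        H = np.concatenate(
            [H, np.zeros((H.shape[0], new_cap - cap), dtype=H.dtype)], axis=1
        )
        s_eff = np.concatenate([s_eff, np.zeros(new_cap - cap)])
        pos = np.concatenate([pos, np.zeros(new_cap - cap)])
    cols = np.arange(n_sites, n_sites + new_count)
    rows = rng.integers(H.shape[0], size=new_count)
    H[:, cols] = 0
    H[rows, cols] = 1
    s_eff[cols] = rng.gamma(k, scale, size=new_count)
    pos[cols] = rng.random(new_count) * L
    return H, s_eff, pos, n_sites + new_count


def _prune(H, s_eff, pos, n_sites, n_haps):
    counts = H[:n_haps, :n_sites].sum(axis=0)
    keep = np.flatnonzero((counts > 0) & (counts < n_haps))
    m = keep.size
    H[:, :m] = H[:, keep]
    s_eff[:m] = s_eff[keep]
    pos[:m] = pos[keep]
    return m


def _linked_wf(rng, sizes, mu_eff, r_eff, L, k, scale, s_cap=0.95):
    """Diploid Wright-Fisher with multiplicative per-allele-copy selection
    (fitness (1-s)^g per site, so the heterozygote pays 1-s and the diffusion
    kernel is exp(-4 Ne s p)), Poisson crossovers, recurrent mutation."""
    N0 = int(sizes[0])
    H = np.zeros((2 * N0, 64), dtype=np.uint8)
    s_eff = np.zeros(64)
    pos = np.zeros(64)
    n_sites = 0
    n_haps = 2 * N0

    for gen, N_next in enumerate(sizes):
        N_next = int(N_next)
        N_cur = n_haps // 2
        # mutation
        n_new = rng.poisson(2 * N_cur * mu_eff * L)
        if n_new:
            H, s_eff, pos, n_sites = _inject_mutations(
                rng, H, s_eff, pos, n_sites, n_new, L, k, scale
            )
        if n_sites == 0:
            n_haps = 2 * N_next
            if H.shape[0] < n_haps:
                H = np.zeros((n_haps, H.shape[1]), dtype=np.uint8)
            continue
        # fitness: w_i = prod_j (1 - s_j)^(g_ij), g in {0,1,2}
        G = (
            H[0 : 2 * N_cur : 2, :n_sites].astype(np.float32)
            + H[1 : 2 * N_cur : 2, :n_sites]
        )
        log_term = np.log1p(-np.minimum(s_eff[:n_sites], s_cap)).astype(
            np.float32
        )
        logw = G @ log_term
        w = np.exp(logw - logw.max())
        prob = w / w.sum()
        # reproduction: two parents per offspring, one recombinant gamete each
        parents = rng.choice(N_cur, size=(N_next, 2), p=prob)
        gametes = np.empty((2 * N_next, n_sites), dtype=np.uint8)
        n_cross = rng.poisson(r_eff * L, size=2 * N_next)
        start = rng.integers(2, size=2 * N_next)
        flat_parents = parents.reshape(-1)  # gamete g comes from this diploid
        no_x = n_cross == 0
        rows = 2 * flat_parents + start
        gametes[no_x] = H[rows[no_x]][:, :n_sites]
        for g in np.flatnonzero(~no_x):
            bp = np.sort(rng.random(n_cross[g]) * L)
            parity = (np.searchsorted(bp, pos[:n_sites]) + start[g]) % 2
            pj = flat_parents[g]
            gametes[g] = np.where(parity == 0, H[2 * pj, :n_sites], H[2 * pj + 1, :n_sites])
        n_haps = 2 * N_next
        if H.shape[0] < n_haps or H.shape[0] > 4 * n_haps:
            H = np.zeros((n_haps, H.shape[1]), dtype=np.uint8)
        H[:n_haps, :n_sites] = gametes
        H[n_haps:, :n_sites] = 0
        # prune fixed/lost sites periodically
        if gen % 10 == 9 or gen == len(sizes) - 1:
            n_sites = _prune(H, s_eff, pos, n_sites, n_haps)

    counts = H[:n_haps, :n_sites].sum(axis=0)
    seg = (counts > 0) & (counts < n_haps)
    return s_eff[:n_sites][seg], counts[seg] / n_haps


def _free_wf(rng, sizes, mu_eff, L, k, scale, s_cap=0.95):
    """Independent-sites Wright-Fisher (free recombination): exact per-locus
    multiplicative (per-copy) selection update followed by binomial drift."""
    x = np.zeros(0, dtype=np.int64)
    s = np.zeros(0)
    N_cur = int(sizes[0])
    for N_next in sizes:
        N_next = int(N_next)
        n_new = rng.poisson(2 * N_cur * mu_eff * L)
        if n_new:
            x = np.concatenate([x, np.ones(n_new, dtype=np.int64)])
            s = np.concatenate([s, rng.gamma(k, scale, size=n_new)])
        if x.size:
            p = x / (2.0 * N_cur)
            sc = np.minimum(s, s_cap)
            waa, wab = (1.0 - sc) ** 2, 1.0 - sc
            wbar = p * p * waa + 2 * p * (1 - p) * wab + (1 - p) ** 2
            p_sel = (p * p * waa + p * (1 - p) * wab) / wbar
            x = rng.binomial(2 * N_next, p_sel)
            seg = (x > 0) & (x < 2 * N_next)
            x, s = x[seg], s[seg]
        N_cur = N_next
    return s, x / (2.0 * N_cur)


def wf_forward_simulate(
    model: EvoModel,
    region_bp: float = 1e6,
    demography: Union[str, Demography] = "constant",
    seed: int = 0,
    rescale: float = 1.0,
    recomb_rate: float = 1e-8,
    linkage: bool = True,
    replicate_id: int = 0,
    burn_in: Optional[int] = None,
) -> SelectedSNPSample:
    """Forward-in-time Wright-Fisher simulation of deleterious mutations.

    Selection coefficients of new mutations are gamma(k, mean s_bar); fitness
    is multiplicative across sites with heterozygote effect s/2. ``rescale``
    applies lambda-rescaling (N/lambda, time/lambda, s*lambda, mu*lambda,
    r*lambda), which preserves 4*Ne*s, 4*Ne*mu and 4*Ne*r; LD-dependent
    quantities under rescaling are approximate. ``linkage=False`` runs an
    exact independent-sites simulator (free recombination). Emitted s values
    are de-rescaled back to the unrescaled scale; non-segregating sites are
    dropped.
    """
    if region_bp < 1e4:
        raise ValueError("region_bp must be at least 1e4")
    rng = np.random.default_rng(seed)
    if demography == "constant":
        demography = Demography.constant(model.Ne, burn_in)
    elif demography == "european":
        demography = Demography.european(N_ancestral=model.Ne)
    sizes = demography.sizes(rescale)
    mu_eff = model.mu * rescale
    r_eff = recomb_rate * rescale
    k = model.k
    scale = model.s_bar * rescale / model.k

    if linkage:
        s_eff, p = _linked_wf(rng, sizes, mu_eff, r_eff, region_bp, k, scale)
    else:
        s_eff, p = _free_wf(rng, sizes, mu_eff, region_bp, k, scale)
    s = s_eff / rescale
    beta2 = model.c * s ** (2.0 * model.tau)
    return SelectedSNPSample(s=s, p=p, beta2=beta2, replicate_id=replicate_id)


# ---------------------------------------------------------------------------
# fitting and tau inference


def fit_alpha_to_effects(
    samples: Union[SelectedSNPSample, Sequence[SelectedSNPSample]],
    maf_min: float,
    n_boot: int = 200,
    seed: int = 0,
    alpha_bounds: Tuple[float, float] = (-3.0, 1.0),
) -> Tuple[float, float, float]:
    """Least-squares fit of c' * [p(1-p)]^alpha to simulated squared effects.

    p is folded to MAF; only SNPs with MAF > maf_min enter (fit above the
    drift threshold T, or above 2T to avoid edge effects near the plateau).
    At fixed alpha the scale c' is
    closed-form, leaving a 1-D search over alpha. The bootstrap standard
    error resamples whole replicates.
    Returns (c_hat, alpha_hat, se_boot).
    """
    if isinstance(samples, SelectedSNPSample):
        samples = [samples]
    mafs, b2s, reps = [], [], []
    for smp in samples:
        m = np.minimum(smp.p, 1.0 - smp.p)
        keep = m > maf_min
        mafs.append(m[keep])
        b2s.append(smp.beta2[keep])
        reps.append(np.full(keep.sum(), smp.replicate_id))
    maf = np.concatenate(mafs)
    b2 = np.concatenate(b2s)
    rep = np.concatenate(reps)
    if maf.size < 100:
        raise ValueError("need at least 100 SNPs above maf_min")
    if np.ptp(maf) == 0:
        raise ValueError("degenerate fit: all frequencies equal")

    logpq = np.log(maf * (1.0 - maf))
    c_hat, alpha_hat = _fit_on_index(logpq, b2, np.arange(maf.size), alpha_bounds)

    rng = np.random.default_rng(seed)
    rep_ids = np.unique(rep)
    if rep_ids.size > 1 and n_boot > 0:
        rep_index = {r: np.flatnonzero(rep == r) for r in rep_ids}
        boots = np.empty(n_boot)
        for b in range(n_boot):
            chosen = rng.choice(rep_ids, size=rep_ids.size, replace=True)
            idx = np.concatenate([rep_index[r] for r in chosen])
            _, boots[b] = _fit_on_index(logpq, b2, idx, alpha_bounds)
        se = float(boots.std(ddof=1))
    else:
        se = np.nan
    return c_hat, alpha_hat, se


def _fit_on_index(logpq, b2, idx, alpha_bounds):
    lp, y = logpq[idx], b2[idx]

    def sse(a):
        w = np.exp(a * lp)
        c = (y * w).sum() / (w * w).sum()
        r = c * w - y
        return float(r @ r)

    res = minimize_scalar(sse, bounds=alpha_bounds, method="bounded")
    a = float(res.x)
    w = np.exp(a * lp)
    return float((y * w).sum() / (w * w).sum()), a


def infer_tau(
    alpha_posterior,
    alpha_of_tau_table,
    alpha_range: Tuple[float, float] = (-1.0, 0.0),
    n_alpha: int = 2001,
    mass: float = 0.95,
):
    """Posterior over the coupling tau given an alpha likelihood curve.

    P(tau | data) ~ integral over alpha of P(alpha | tau) P(alpha | data),
    with flat priors on alpha over [-1, 0] and tau over [0, 1]. The table maps
    each tau grid value to the mean and se of the alpha fitted in forward
    simulations (several rows per tau — e.g. one per s_bar — are mixed with
    equal weight). ``alpha_posterior`` may be an AlphaFitResult-like object
    (with .posterior()) or a (mean, sd) tuple.

    Returns (tau_grid, posterior_density, (lo, hi) central interval).
    """
    import pandas as pd

    tbl = pd.DataFrame(alpha_of_tau_table)
    required = {"tau", "alpha_mean", "alpha_se"}
    if not required.issubset(tbl.columns):
        raise ValueError(f"table needs columns {sorted(required)}")
    taus = np.sort(tbl["tau"].unique())
    if taus.min() > 0.0 + 1e-9 or taus.max() < 1.0 - 1e-9:
        raise ValueError("alpha_of_tau_table must cover tau in [0, 1]")

    a = np.linspace(alpha_range[0], alpha_range[1], n_alpha)
    if hasattr(alpha_posterior, "posterior"):
        x, dens = alpha_posterior.posterior()
        p_data = np.interp(a, x, dens, left=0.0, right=0.0)
    else:
        mean, sd = alpha_posterior
        p_data = norm.pdf(a, mean, sd)
    z = np.trapezoid(p_data, a)
    if z <= 0:
        raise ValueError("alpha posterior has no mass on the alpha range")
    p_data /= z

    post = np.empty(taus.size)
    for i, t in enumerate(taus):
        rows = tbl[tbl["tau"] == t]
        p_alpha_tau = np.zeros_like(a)
        for _, r in rows.iterrows():
            p_alpha_tau += norm.pdf(a, r["alpha_mean"], r["alpha_se"])
        p_alpha_tau /= len(rows)
        post[i] = np.trapezoid(p_alpha_tau * p_data, a)
    z = np.trapezoid(post, taus)
    post = post / z
    cdf = np.concatenate(
        [[0.0], np.cumsum((post[1:] + post[:-1]) / 2 * np.diff(taus))]
    )
    cdf /= cdf[-1]
    lo = float(np.interp((1 - mass) / 2, cdf, taus))
    hi = float(np.interp(1 - (1 - mass) / 2, cdf, taus))
    return taus, post, (lo, hi)
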