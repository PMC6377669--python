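# Methods

## The alpha model

`alphafreq` works with the random-effect model of MAF-dependent genetic
architecture. For a trait measured on N individuals genotyped at M SNPs,

    y = X beta + eps,   eps_i ~ N(0, sigma_eps^2) i.i.d.,
    beta_j | p_j ~ N(0, sigma_g_alpha^2 * [2 p_j (1 - p_j)]^alpha),

where `X` is the mean-centered dosage matrix and `p_j` the minor allele
frequency (MAF) of SNP j. `alpha < 0` means rarer variants carry larger
per-allele effects; `alpha = 0` means no frequency dependence. Under this
model the phenotype is multivariate normal,

    y ~ N(0, sigma_g_alpha^2 * K(alpha) + sigma_eps^2 * I),
    K(alpha) = X D_alpha X^T,  (D_alpha)_jj = [2 p_j (1 - p_j)]^alpha,

and the expected heritability contributed by a SNP of frequency p is
proportional to `[2p(1-p)]^(1+alpha)`.

## Estimation

For each alpha on a grid (default −1.00 to 0.00 in steps of 0.05) the two
variance components are estimated by REML: the fixed effects (always
including an intercept) are projected out with an orthonormal complement
basis, the projected kernel is eigendecomposed once, the total variance is
profiled out in closed form, and the variance ratio is found by bounded
Brent search on its logarithm. The resulting profile log-likelihood curve is
extended beyond the initial grid — in both directions, capped at [−2, 1] —
until the mode-to-boundary gap reaches 5 log-units, then interpolated with a
natural cubic spline; the estimate is the spline argmax (dense evaluation at
step 1e-4). Combining the curve with a flat prior yields the posterior used
for the 95% credible interval (equal-tailed by default; an HPD option
exists) and for the posterior-sd standard error used in meta-analysis. A
curve whose total range is below 0.5 log-units is flagged flat and returns
no estimate. Large cohorts can be split into disjoint batches whose
restricted log-likelihoods are summed; this trades a modest amount of
information for linear memory.

Numerical notes: variance components are constrained nonnegative (boundary
fits are flagged); the ratio search runs over [1e-6, 1e6]; zero-variance
SNPs are dropped from the GRM with a logged count; any positive rescaling of
the GRM only rescales sigma_g^2 and is recorded as a normalizer, leaving the
alpha curve unchanged (property-tested). The GRM product may be computed in
float32 for large design matrices; the resulting log-likelihood perturbation
is orders of magnitude below Monte-Carlo noise (verified against float64).

## LD-dependent weights

At a given MAF, high-LD SNPs have systematically smaller causal effects. The
level of LD (LLD) is the rank-based inverse normal transform of the windowed
LD score (sum of adjusted squared correlations, r2 − (1−r2)/(N−2), self
term included; 1000 kb window by default), standardized within each of 20
MAF-quantile bins so LLD is independent of MAF by construction. The
effect-variance model gains a factor `(1 + tau* · LLD_j)` with `tau* = −0.3`
by default; estimation absorbs it by scaling dosage column j by
`max(0, 1 + tau* · LLD_j)^(1/2)`. The multiplier is clamped at zero because
LLD is unbounded. `tau*` can also be profiled jointly with alpha on a 2-D
grid (default tau* in {−0.60, −0.45, −0.30, −0.15, 0}).

## Heritability

With the reweighted columns, per-normalized-allele effects are i.i.d., so
REML recovers `sigma_g_alpha^2` without frequency-dependence bias. The
genetic variance is `A · sigma_g_alpha^2` with
`A = sum_j [2 p_j (1-p_j)]^(1+alpha)` (times `(1 − 0.3 LLD_j)` in the
LD-weighted variant — the squared column weight enters A once), giving

    h2 = A s_g2 / (A s_g2 + s_e2).

The fraction of SNP-heritability below a MAF cutoff is the
`[2p(1-p)]^(1+alpha)`-weighted mass of an allele-frequency spectrum below
the cutoff; spectra may be per-SNP, binned counts, or analytic densities
(integrated by trapezoid on log-spaced grids split exactly at the cutoff).
Uncertainty in alpha propagates by Monte Carlo over a truncated normal on
[−2, 1]. Fraction estimates quoted for real cohorts depend on that cohort's
reference allele-frequency spectrum; the package ships the machinery and
accepts any spectrum, not a particular cohort's.

## Cross-trait synthesis

The cross-trait mean is the inverse-variance-weighted average. Heterogeneity
is tested by `sum_i (a_i − a_cross)^2 / se_i^2` against a chi-square with n
degrees of freedom — the stated convention of the method; since the mean is
estimated, the classical null is chi-square with n−1 df, so an `n−1` option
is provided and the default is documented as conservative (null simulations
in the test suite quantify both). The dispersion of true alpha across traits
is the sd under a normal model for which simulated estimate sets (true
spread plus per-trait noise) match the observed variance; common random
numbers make the objective monotone so bisection applies, the
method-of-moments value `max(0, var − mean(se^2))` seeds the bracket, and a
parametric bootstrap gives its standard error.

## Synthetic data

The generator emulates the features of imputed cohort genotype data that the
estimator is sensitive to: a rare-variant-skewed MAF spectrum (density
proportional to 1/p truncated at 0.0007), local LD from a stationary
Gaussian-copula AR(1) haplotype model whose latent correlation decays as
exp(−d / 25 kb) with ~1 kb mean SNP spacing, sparse causal architecture
(default 1% of SNPs causal, chosen uniformly at random), effect variances
following the alpha model with the `(1 + tau* LLD)` multiplier clamped at
zero, environmental noise scaled to hit the target h2 exactly in
realization, and calibrated imputation noise: probability triples are built
by blending the true hard genotype with a Hardy-Weinberg prior at weight
1 − calibration (default calibration 0.8), phenotypes are generated from
hard genotypes resampled from the triples while inference uses the expected
dosages. Sample-monomorphic draws are forced to carry one heterozygote.
Below a simulation threshold T_sim the effect variance can be frozen at its
value at T_sim.

What it does not emulate: real recombination-hotspot block structure,
MAF-dependent imputation quality, population stratification, relatedness,
and genome-scale SNP counts. Passing recovery tests therefore show the
estimator is consistent under its own model assumptions at the simulated
scale; they do not certify behavior on biobank data.

## Evolutionary layer

Under the Eyre-Walker coupling `E(beta^2 | s) = c * s^(2 tau)` with a gamma
distribution of fitness effects (mean `s_bar`, shape `k`) and the diffusion
frequency kernel `P(p|s) ~ [p(1-p)]^{-1} exp(−4 Ne s p)`,

    E(beta^2 | p) = c * G(2 tau + k)/G(k) * (4 Ne)^(−2 tau) * (p + T)^(−2 tau),
    T = k / (4 Ne s_bar).

Below the drift threshold T effects plateau; far above T they fall off as
`p^(−2 tau)`, so the alpha model holds with `alpha ≈ −2 tau` in this no-LD,
constant-size limit. The MAF-symmetrized form mixes the minor- and
major-derived branches of the same kernel exactly:

    E(beta^2 | MAF p) = c * G(2tau+k)/G(k) * (4Ne)^(−2tau) *
        [(p+T)^(−2tau−k) + (1−p+T)^(−2tau−k)] / [(p+T)^(−k) + (1−p+T)^(−k)].

Two consequences matter for testing. First, the folded form differs from the
derived form at small MAF by a non-negligible level factor (about 20% at
k = 0.25): the folded spectrum keeps mass from weakly selected derived
alleles near fixation. Second, fitting `c' [p(1−p)]^alpha` to the exact
folded curve above 2T with the least-squares procedure used throughout
yields a best-fit alpha of −0.74 at (tau=0.4, k=0.25, s_bar=1e-3, Ne=1e4),
not the asymptotic −0.80; the simulation tests compare against both, with
the theory-implied value as the primary anchor.

The forward simulator is a diploid Wright-Fisher model with recurrent
mutation (rate 2e-8 per bp per generation), Poisson crossovers (rate 1e-8
per bp), and multiplicative per-allele-copy fitness `(1 − s)^g` — the
convention matching the analytic kernel above. Selection coefficients of
new mutations are gamma(k, mean s_bar). Demography is either constant Ne
(default burn-in 10 Ne generations) or a three-epoch European model:
ancestral Ne = 10,000 with a 3,880-generation burn-in, a bottleneck of
Ne = 2,000 for 1,000 generations, and exponential growth to Ne = 50,000
over 900 generations; all epoch parameters are configurable. Lambda
rescaling (Ne/λ, time/λ, s·λ, mu·λ, r·λ) preserves 4Ne·{s, mu, r} and is
used to bring runs to desk scale; LD-dependent quantities are then
approximate, and sites with rescaled s near 1 are capped at 0.95. A
free-recombination variant simulates sites independently with the exact
per-locus selection update (used for analytic cross-validation). Fixed and
lost sites are pruned; emitted selection coefficients are de-rescaled.

`fit_alpha_to_effects` minimizes the squared deviation between
`c' [p(1−p)]^alpha` and per-SNP squared effects (MAF-folded) above a
frequency cutoff, with c' closed-form at fixed alpha and bootstrap standard
errors over whole replicates. `infer_tau` turns a table of simulated
(tau → fitted alpha mean, se) pairs — mixed with equal weight over s_bar
settings — and an alpha likelihood curve into a posterior on tau via
`P(tau|data) ∝ ∫ P(alpha|tau) P(alpha|data) d alpha` with flat priors on
alpha over [−1, 0] and tau over [0, 1].

## Phenotype preprocessing

Fixed order: single-pass removal of values ≥ 4 sample-sd from the mean, OLS
residualization on the covariates (intercept always included; collinear
columns resolved by least squares), then the rank-based inverse normal
transform with the Blom offset 3/8 (ties get mean ranks; all-equal input
maps to zeros).

## Problem sizes used by the test suite

The recovery studies run at reduced scale so the full suite completes on one
CPU: N = 1,000 individuals, M = 8,000 SNPs, an alpha grid of step 0.3 with
the gap-of-5 extension rule, float32 GRM products, and 10–20 replicates per
setting; forward simulations use lambda = 10 rescaling with 0.3 Mb regions
and 6–8 replicates. At this scale the per-replicate spread of the alpha
estimate is large (empirically sd ≈ 0.3–0.5 at 1% polygenicity), so
mean-recovery checks carry Monte-Carlo standard errors of roughly 0.1 per
setting; the test suite documents which checks are expected to be binding at
this precision. The estimator itself has no scale-specific logic: the same
code paths run at cohort scale with a finer grid.

## Known limitations

- The profile curve at low power is flat-topped above the mode, so the
  spline argmax has a right-skewed error distribution at small N·h2; grid
  capping truncates but does not remove this skew.
- The credible interval normalizes over the sampled alpha range only.
- Ascertained case-control traits are out of scope (the mixed model needs a
  liability-scale treatment the package does not provide).
- The standard error of `alpha_common − alpha` on a single dataset sums the
  two posterior variances and is conservative because the curves share data.
- The gamma-DFE kernel `exp(−4 Ne s p)` is itself a weak-selection
  approximation; near-fixation behavior of strongly selected alleles is not
  captured by the folded closed form (the simulator is the arbiter there).
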