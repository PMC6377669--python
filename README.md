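# alphafreq

Estimation and evolutionary interpretation of MAF-dependent genetic
architectures.

## The problem

Rare variants can carry larger per-allele effects on complex traits than
common ones, a signature of negative selection. `alphafreq` quantifies this
with the single-parameter *alpha model*: the per-allele effect of a SNP with
minor allele frequency *p* is a random draw

&nbsp;&nbsp;&nbsp;&nbsp;β | p ~ N(0, σ²_{g,α} · [2p(1−p)]^α),

so α < 0 means larger effects for rarer variants and the heritability
contributed by a SNP scales as [2p(1−p)]^{1+α}. The package is written for
statistical geneticists who want to

- **estimate α** from individual-level genotype/phenotype data with a
  profile-likelihood mixed model: for each α on a grid the phenotype
  covariance σ²_{g,α}·XD_αXᵀ + σ²_ε·I is fit by REML, the curve is splined
  and its mode, flat-prior credible interval and standard error reported —
  with LD-dependent SNP weights (1 + τ*·LLD) to avoid bias from LD-dependent
  causal effects;
- **correct SNP-heritability** for MAF- and LD-dependent architecture
  (ĥ² = Âσ̂²_{g,α}/(Âσ̂²_{g,α}+σ̂²_ε) with Â = Σ[2p(1−p)]^{1+α̂}) and
  partition it across the MAF spectrum;
- **synthesize α across traits** (inverse-variance-weighted mean,
  heterogeneity χ² test, best-fit dispersion of true α);
- **interpret α through selection**: under the Eyre-Walker coupling
  E(β²|s) = c·s^{2τ} with a gamma distribution of fitness effects,
  E(β²|p) ∝ (p + T)^{−2τ} with the drift threshold T = k/(4Nₑs̄); the
  package evaluates the closed forms, runs Wright-Fisher forward simulations
  (with linkage, demography, and population rescaling), fits α to simulated
  effects, and inverts the α–τ relationship into a posterior on τ.

A seeded synthetic-data module generates LD-bearing dosage panels with
rare-skewed MAF spectra, calibrated imputation noise and α-model phenotypes,
so the whole pipeline is testable end to end without external data.

## Worked example

```python
import numpy as np
from alphafreq import SimConfig, simulate_genotypes, simulate_phenotype
from alphafreq import compute_ld_scores, compute_lld
from alphafreq.profile import AlphaModel

cfg = SimConfig(n_samples=1000, n_snps=8000, alpha=-0.5, h2=0.5,
                prop_causal=1.0, tau_star=-0.3, seed=42)
panel = simulate_genotypes(cfg)
lld = compute_lld(compute_ld_scores(panel), panel.maf).lld
trait = simulate_phenotype(panel, cfg, lld=lld)

model = AlphaModel(grid_start=-1.2, grid_stop=0.2, grid_step=0.2)
model.fit(panel, trait.phenotype, lld=lld)
print(f"alpha_hat = {model.alpha_hat_:.3f}")
print(f"95% CI    = ({model.ci95_[0]:.3f}, {model.ci95_[1]:.3f})")
print(f"h2        = {model.h2_:.3f}")
```

```
alpha_hat = -0.639
95% CI    = (-0.842, -0.323)
h2        = 0.582
```

The credible interval covers the simulated α = −0.5 (a single cohort of
1,000 samples carries limited information about α, which the interval
reflects); `h2_` is the bias-corrected SNP-heritability at the estimated α,
near the simulated 0.5. The
estimator follows the scikit-learn `fit`/`get_params` convention, and every
step is also available as plain functions (`profile_likelihood`,
`estimate_h2`, `ivw_mean`, `wf_forward_simulate`, ...).

The evolutionary layer in three lines:

```python
from alphafreq import EvoModel, threshold_T, gamma_dfe_stats
m = EvoModel(tau=0.4, s_bar=1e-3, k=0.25, Ne=10_000)
print(threshold_T(m), gamma_dfe_stats(0.0625, 1e-3)[2])
```

```
0.00625 6940.09884046823
```

— below MAF ≈ 0.006 drift dominates and effect sizes plateau; at DFE shape
k = 0.0625 the mean fitness effect is ~6,900× the median (extremely sparse
fitness architecture).

A command-line interface mirrors the library:
`alphafreq simulate | lld | estimate | pheno | h2frac | meta | evolve |
fit-evo | infer-tau` (see `alphafreq --help`).

## Scope notes

Case-control liability-scale analysis, BGEN parsing, and curation heuristics
for real cohort phenotypes (heritability screens, trait deduplication) are
out of scope; preprocessing covers outlier removal, covariate regression and
the rank-based inverse normal transform.
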