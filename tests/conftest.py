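import numpy as np
import pytest

from alphafreq import SimConfig, simulate_genotypes


@pytest.fixture(scope="session")
def small_panel():
    """Small LD-bearing panel shared across cheap tests."""
    cfg = SimConfig(n_samples=200, n_snps=300, seed=11, mean_spacing_bp=500.0)
    return simulate_genotypes(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def hwe_panel(rng, n, m, maf_low=0.05, maf_high=0.5):
    """Independent Hardy-Weinberg genotypes (no LD), polymorphic columns."""
    from alphafreq import GenotypePanel

    p = rng.uniform(maf_low, maf_high, m)
    G = rng.binomial(2, p, size=(n, m)).astype(float)
    maf = G.mean(0) / 2
    flip = maf > 0.5
    G[:, flip] = 2 - G[:, flip]
    maf = np.where(flip, 1 - maf, maf)
    ok = G.std(0) > 0
    return GenotypePanel(G[:, ok], maf[ok], np.arange(1, ok.sum() + 1) * 1000)
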