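import numpy as np
import pytest

from evoscales.popgen_stats import HaplotypeMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def random_hm(rng):
    """Small random haplotype matrix (12 hap x 30 sites, all polymorphic)."""
    n_hap, n_sites = 12, 30
    while True:
        a = (rng.random((n_hap, n_sites)) < rng.uniform(0.2, 0.8, n_sites)).astype(
            np.uint8
        )
        f = a.mean(axis=0)
        if ((f > 0) & (f < 1)).all():
            break
    pos = np.sort(rng.choice(100_000, size=n_sites, replace=False)).astype(np.int64)
    return HaplotypeMatrix(a, pos, chrom="t", length=100_000)


@pytest.fixture(scope="session")
def pheno_series():
    """Default synthetic 26-year series with the early-plateau + step shape."""
    from evoscales.synthetic_data import PhenoSimConfig, generate_phenotypes

    return generate_phenotypes(PhenoSimConfig(seed=4))
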