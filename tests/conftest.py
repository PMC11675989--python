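import numpy as np
import pandas as pd
import pytest

from fearscan import simdata


@pytest.fixture(scope="session")
def small_cohort():
    """3-breed, 150-dog, 400-SNP cohort with phenotypes; shared across tests."""
    cfg = simdata.SimConfig(
        n_breeds=3, n_per_breed=50, n_snps=400, n_chromosomes=10,
        missing_rate=0.01, n_causal=5, h2_target=0.3, seed=7,
    )
    geno, variants, samples, truth = simdata.simulate_genotypes(cfg)
    behav, truth = simdata.simulate_phenotypes(geno, samples, cfg, truth)
    return dict(cfg=cfg, geno=geno, variants=variants, samples=samples,
                behavior=behav, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
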