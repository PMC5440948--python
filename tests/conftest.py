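import numpy as np
import pytest

from exlwgs import calling, cohort, reads
from exlwgs.cohort import PopulationSpec, StratumSpec


@pytest.fixture(scope="session")
def small_cohort():
    """One-population founder-mosaic cohort, 40 samples x 800 sites."""
    strata = [StratumSpec("pop", 40, (1.0,), {"M": 1.0})]
    pops = [PopulationSpec("P0", 0.015, 8)]
    return cohort.assemble_cohort(
        strata=strata,
        populations=pops,
        n_sites=800,
        region_length=800_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pileup(small_cohort):
    return reads.simulate_cohort_pileups(
        small_cohort, reads.DepthModel(error_rate=0.005), seed=12
    )


@pytest.fixture(scope="session")
def small_gl(small_pileup):
    return calling.genotype_likelihoods_from_counts(
        small_pileup.n_ref, small_pileup.n_alt, 0.005
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
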