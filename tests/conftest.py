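import numpy as np
import pytest
from hypothesis import settings

import geascan as g

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def env_table():
    return g.load_nsw_env_table()


@pytest.fixture(scope="session")
def small_admixed():
    """3 demes x 20 individuals x 400 loci, moderate differentiation."""
    return g.gen_admixed_genotypes(3, 20, 400, fst=0.1, seed=101)


@pytest.fixture(scope="session")
def planted_dataset(env_table):
    """13 demes mirroring the NSW meadows with 40 loci planted on AvTemp."""
    matrix, truth = g.gen_admixed_genotypes(
        13, 26, 1000, fst=0.05, seed=202, site_names=list(env_table.index)
    )
    truth.adaptive_loci = list(range(40))
    truth.beta = 2.0
    matrix = g.plant_env_effects(matrix, truth, env_table["AvTemp"].to_numpy(), seed=203)
    return matrix, truth
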