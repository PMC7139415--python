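import numpy as np
import pytest

from gfscan import (
    build_index_matrix,
    enumerate_conditions,
    generate_cohort,
    simulate_readouts,
)


@pytest.fixture(scope="session")
def catalog():
    return enumerate_conditions()


@pytest.fixture(scope="session")
def cohort():
    return generate_cohort(seed=7)


@pytest.fixture(scope="session")
def readouts(cohort, catalog):
    return simulate_readouts(cohort, catalog, seed=7)


@pytest.fixture(scope="session")
def gim(readouts, catalog):
    return build_index_matrix(readouts, catalog)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260923)
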