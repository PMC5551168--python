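import numpy as np
import pytest

from tractrisk.regression import load_table1_fixture
from tractrisk.synthgen import (
    GenParams,
    TrueModelSet,
    assign_upstream_behaviors,
    generate_ground_truth,
    simulate_survey,
)


@pytest.fixture(scope="session")
def truth():
    return TrueModelSet.default()


@pytest.fixture(scope="session")
def table1():
    return load_table1_fixture()


@pytest.fixture(scope="session")
def toy_city():
    """4-tract, low-diversity city; exact constraint matching is feasible."""
    return generate_ground_truth(GenParams.toy(4, 30, rng_seed=2))


@pytest.fixture(scope="session")
def small_city(truth):
    """6-tract mid-size city with behaviors assigned to adults."""
    pop = generate_ground_truth(
        GenParams.default(n_tracts=6, households_per_tract=150, rng_seed=11)
    )
    return assign_upstream_behaviors(pop, truth, 12)


@pytest.fixture(scope="session")
def small_survey(small_city, truth):
    return simulate_survey(small_city, truth, 2000, 13)


@pytest.fixture(scope="session")
def big_city(truth):
    """Full-size 31-tract city: ~30k residents, ~22k adults."""
    pop = generate_ground_truth(
        GenParams.default(n_tracts=31, households_per_tract=400, rng_seed=101)
    )
    return assign_upstream_behaviors(pop, truth, 102)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
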