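import logging

import numpy as np
import pytest

from landcarbon import fixtures as fx
from landcarbon.driver import build_parameters
from landcarbon.engine import DisturbanceMatrix, FlowParams
from landcarbon.params import ExpansionParams, get_species
from landcarbon.spinup import SpinupConfig

logging.getLogger("landcarbon").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def flows():
    return FlowParams.from_tables()


@pytest.fixture(scope="session")
def matrices():
    return DisturbanceMatrix.load()


@pytest.fixture(scope="session")
def douglas_fir():
    return get_species("Douglas-fir")


@pytest.fixture(scope="session")
def expansion(douglas_fir):
    return ExpansionParams.for_species(douglas_fir.species_name)


@pytest.fixture(scope="session")
def params_df():
    """Parameter set for Douglas-fir only, full spin-up."""
    return build_parameters(species_names=["Forest: Douglas-fir Group"])


@pytest.fixture(scope="session")
def params4():
    """Parameter set covering the default 4-species fixture mix."""
    return build_parameters(species_names=list(fx.DEFAULT_SPECIES))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_pools(rng, n, scale=50.0):
    """Random non-negative pool states for property tests."""
    return rng.uniform(0.0, scale, size=(n, 14))
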