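import numpy as np
import pytest
from hypothesis import settings

from epifold.energetics import PotentialParams, default_contact_table
from epifold.dynamics import ThermostatParams
from epifold.fixtures import make_fixture, SHIPPED_SEED

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    return PotentialParams()


@pytest.fixture(scope="session")
def thermostat():
    return ThermostatParams()


@pytest.fixture(scope="session")
def table():
    return default_contact_table()


@pytest.fixture(scope="session")
def folder_fixture():
    """The shipped minimal-folder system (folds once per session)."""
    return make_fixture("minimal-folder", SHIPPED_SEED)


@pytest.fixture(scope="session")
def docking_toy():
    return make_fixture("docking-toy", SHIPPED_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
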