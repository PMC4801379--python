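"""Shared fixtures.

Expensive simulation products (the verification run and the three
experiments at full scale) are session-scoped so the acceptance tests and
the unit tests share one computation. All seeds are fixed.
"""

import numpy as np
import pytest

import canopyfly as cf
from canopyfly.fixtures import make_empty_canopy, make_fixture_canopy

SESSION_SEED = 11


@pytest.fixture(scope="session")
def closed_canopy():
    return cf.build_canopy("closed", 7)


@pytest.fixture(scope="session")
def vase_canopy():
    return cf.build_canopy("vase", 7)


@pytest.fixture(scope="session")
def central_canopy():
    return cf.build_canopy("fruit_centralized", 7)


@pytest.fixture()
def spec():
    return cf.SensingSpec()


@pytest.fixture()
def tiny_canopy():
    return make_fixture_canopy()


@pytest.fixture()
def empty_canopy():
    return make_empty_canopy()


@pytest.fixture(scope="session")
def verification():
    return cf.run_verification(SESSION_SEED)


@pytest.fixture(scope="session")
def architecture():
    return cf.experiment_architecture(SESSION_SEED)


@pytest.fixture(scope="session")
def fruit_position():
    return cf.experiment_fruit_position(SESSION_SEED)


@pytest.fixture(scope="session")
def entry_point():
    return cf.experiment_entry_point(SESSION_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
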