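import numpy as np
import pytest

from atpfret.bioenergetics import ARCHETYPES, simulate_cell
from atpfret.fluorescence import AcquisitionModel, DEFAULT_SENSORS
from atpfret.protocols import make_protocol


@pytest.fixture(scope="session")
def hela():
    return ARCHETYPES["hela_like"]


@pytest.fixture(scope="session")
def beta():
    return ARCHETYPES["beta_like"]


@pytest.fixture(scope="session")
def removal_protocol():
    return make_protocol("glucose_removal")


@pytest.fixture(scope="session")
def hela_removal_sim(hela, removal_protocol):
    """One HeLa-like cell through the glucose-removal protocol (shared)."""
    return simulate_cell(hela, removal_protocol)


@pytest.fixture(scope="session")
def fingerprint_protocol():
    return make_protocol("glc_removal_then_oligo")


@pytest.fixture
def clean_acq():
    """Noise-, bleach- and background-free acquisition."""
    return AcquisitionModel(noise_sd=0.0, bg_cfp=0.0, bg_yfp=0.0)


@pytest.fixture
def mito_sensor():
    return DEFAULT_SENSORS["mito"]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
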