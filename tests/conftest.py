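import numpy as np
import pytest

from fidnav.preprocess import FidnavSeries
from fidnav.simulate import NoiseModel, make_coil_array, make_phantom


@pytest.fixture(scope="session")
def phantom():
    return make_phantom()


@pytest.fixture(scope="session")
def coils(phantom):
    return make_coil_array(phantom, n_channels=32, seed=1)


@pytest.fixture(scope="session")
def small_coils(phantom):
    return make_coil_array(phantom, n_channels=8, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noiseless():
    return NoiseModel.noiseless()


def make_series(signal, tr_seconds=1.54, n_steps=None):
    """Helper building a FidnavSeries from a (n_channels, n_tr) array."""
    return FidnavSeries(signal=np.asarray(signal, dtype=complex),
                        tr_seconds=tr_seconds, n_steps=n_steps)
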