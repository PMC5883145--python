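import numpy as np
import pytest

from fwta import NetworkParameters


@pytest.fixture(scope="session")
def params():
    """Default network parameters (200 units)."""
    return NetworkParameters()


@pytest.fixture(scope="session")
def small_params():
    """A 20-unit network for cheap integration tests."""
    return NetworkParameters(n_units=20)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
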