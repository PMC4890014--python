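import numpy as np
import pytest
from hypothesis import settings

from visipd import build_ba_network, build_square_lattice

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_lattice():
    return build_square_lattice(6, "periodic")


@pytest.fixture(scope="session")
def small_ba():
    return build_ba_network(120, 2, np.random.default_rng(99))
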