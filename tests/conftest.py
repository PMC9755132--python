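import numpy as np
import pytest

from pnpqsm import build_dipole_kernel, make_brainlike_phantom
from pnpqsm.volume import VolumeGrid


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def kernel16():
    return build_dipole_kernel((16, 16, 16))


@pytest.fixture(scope="session")
def kernel48():
    return build_dipole_kernel((48, 48, 48))


@pytest.fixture(scope="session")
def brain48():
    """Small brain-like phantom shared across solver/metric tests."""
    return make_brainlike_phantom(7, shape=(48, 48, 48))


@pytest.fixture()
def random_volume(rng):
    return VolumeGrid(rng.normal(size=(8, 8, 8)))
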