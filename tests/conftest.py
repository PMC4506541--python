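import numpy as np
import pytest

from picoem.core import AcquisitionParams
from picoem.simulator import PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def phantom64():
    """Default barrel phantom in a 64-voxel box (2.8 A/voxel)."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def phantom32():
    """Coarse 32-voxel phantom (5.6 A/voxel) for reconstruction oracles."""
    return build_phantom(PhantomSpec(box_size=32, voxel_size=5.6))


@pytest.fixture(scope="session")
def acq28():
    """Acquisition parameters at the phantom's 2.8 A pixel size."""
    return AcquisitionParams(pixel_size=2.8)


@pytest.fixture(scope="session")
def acq56():
    return AcquisitionParams(pixel_size=5.6)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
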