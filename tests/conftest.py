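import numpy as np
import pytest

from probinitio.fourier import DensityVolume
from probinitio.simulate import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom48() -> DensityVolume:
    return make_phantom(PhantomSpec(box=48, pixel_size=2.0, seed=5))[0]


@pytest.fixture(scope="session")
def phantom64() -> DensityVolume:
    return make_phantom(PhantomSpec(box=64, pixel_size=2.0, seed=5))[0]


@pytest.fixture(scope="session")
def phantom32() -> DensityVolume:
    return make_phantom(PhantomSpec(box=32, pixel_size=3.0, seed=7))[0]
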