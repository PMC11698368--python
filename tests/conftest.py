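import numpy as np
import pytest

from neurovol.phantom import PhantomSpec, make_phantom
from neurovol.volume_io import Patch, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def blob_volume_64():
    """64-cube anatomy-like phantom: smooth foreground, exact-zero background."""
    return make_phantom(PhantomSpec(shape=(64, 64, 64), kind="gaussian_blobs",
                                    n_structures=3, seed=0))


@pytest.fixture(scope="session")
def bandlimited_32():
    """32-cube band-limited texture, lossless under 1/2 downsampling."""
    return make_phantom(PhantomSpec(shape=(32, 32, 32), kind="bandlimited_noise",
                                    cutoff_fraction=0.4, seed=7))


@pytest.fixture(scope="session")
def smooth_patch_16():
    vol = make_phantom(PhantomSpec(shape=(16, 16, 16), kind="gaussian_blobs",
                                   n_structures=2, seed=3))
    return Patch(origin=(0, 0, 0), size=16, data=vol.data)
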