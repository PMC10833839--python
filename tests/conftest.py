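import numpy as np
import pytest

from craniomorph import phantom
from craniomorph.volumes import VolumeImage


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_pair():
    """A small noisy phantom pair shared by fast registration-level tests."""
    spec = phantom.PhantomSpec(shape=(32, 32, 32), spacing=5.0, seed=1, max_displacement=6.0)
    return phantom.generate_pair(spec)


@pytest.fixture()
def random_volume(rng):
    data = rng.normal(0.0, 100.0, size=(9, 9, 9))
    return VolumeImage(data=data, spacing=[1.0, 2.0, 0.5], origin=[-4.0, -8.0, -2.0])
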