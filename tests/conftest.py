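import numpy as np
import pytest

from oralseg.label_scheme import default_scheme
from oralseg.phantom import PhantomSpec, generate_phantom
from oralseg.volume_io import LabelVolume, Volume


@pytest.fixture(scope="session")
def scheme():
    return default_scheme()


@pytest.fixture(scope="session")
def small_phantom():
    """Coarse desk phantom: full 36-structure scene on a 32-voxel cube."""
    return generate_phantom(PhantomSpec(grid_shape=(32, 32, 32),
                                        spacing_mm=1.2, seed=42))


@pytest.fixture(scope="session")
def midsize_phantom():
    return generate_phantom(PhantomSpec(grid_shape=(48, 48, 40),
                                        spacing_mm=0.8, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_label_pair(rng, shape=(5, 5, 5), n_classes=4, spacing=(1., 1., 1.)):
    pred = LabelVolume(labels=rng.integers(0, n_classes + 1, size=shape,
                                           dtype=np.int16), spacing=spacing)
    gt = LabelVolume(labels=rng.integers(0, n_classes + 1, size=shape,
                                         dtype=np.int16), spacing=spacing)
    return pred, gt
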