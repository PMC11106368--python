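import numpy as np
import pytest

from lcseg.io_core import BinaryMask, Volume
from lcseg.phantom import PhantomSpec, make_cohort, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """Single default-spec phantom, seed 1 (the calibration reference)."""
    return make_phantom(PhantomSpec(seed=1))


@pytest.fixture(scope="session")
def cohort6():
    """Six-case site-A cohort used by the LOOCV checks."""
    return make_cohort(6, base_seed=7, site="A")


@pytest.fixture(scope="session")
def cohort20():
    """Twenty-case cohort for the volume-ratio and symmetry sweeps."""
    return make_cohort(20, base_seed=7, site="A")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_volume(data, voxel=1.0, origin=None):
    data = np.asarray(data, dtype=float)
    aff = np.diag([voxel, voxel, voxel, 1.0])
    if origin is not None:
        aff[:3, 3] = origin
    return Volume(data, aff)


def make_binary(data, voxel=1.0):
    v = make_volume(data, voxel)
    return BinaryMask(v.data.astype(np.uint8), v.affine)
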