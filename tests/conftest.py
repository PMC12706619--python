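import numpy as np
import pytest

from evansindex import EIConfig, LabelVolume, LandmarkSet, compute_evans_index
from evansindex.phantom import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """(lv, icv, landmarks, truth) for the default 0.30-EI phantom."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def default_ei_result(default_phantom):
    lv, icv, landmarks, _ = default_phantom
    return compute_evans_index(lv, icv, landmarks, EIConfig())


def make_volume(shape=(10, 10, 10), spacing=1.0, origin=None, marks=()):
    """Small axis-aligned test volume with voxels set at ``marks``."""
    grid = np.zeros(shape, dtype=np.uint8)
    for ix in marks:
        grid[tuple(ix)] = 1
    affine = np.diag([spacing, spacing, spacing, 1.0])
    if origin is None:
        origin = [-spacing * (s - 1) / 2.0 for s in shape]
    affine[:3, 3] = origin
    return LabelVolume(grid, affine)


def make_sphere_volume(radius=20.0, spacing=1.0, pad=8, center=(0.0, 0.0, 0.0)):
    n = int(2 * ((radius + pad) // spacing) + 1)
    vol = make_volume((n, n, n), spacing)
    A = vol.affine
    i = np.arange(n)
    X = (A[0, 0] * i + A[0, 3]).reshape(-1, 1, 1) - center[0]
    Y = (A[1, 1] * i + A[1, 3]).reshape(1, -1, 1) - center[1]
    Z = (A[2, 2] * i + A[2, 3]).reshape(1, 1, -1) - center[2]
    grid = ((X**2 + Y**2 + Z**2) <= radius**2).astype(np.uint8)
    return LabelVolume(grid, vol.affine)


@pytest.fixture
def centered_landmarks():
    return LandmarkSet(ac=(0.0, 10.0, 0.0), pc=(0.0, -10.0, 0.0), ivf=(0.0, 0.0, 2.0))
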