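import numpy as np
import pytest

from neuroskel.seed_segment import SeedInstance, SeedSet
from neuroskel.sparse_grid import SparseMask


def make_shell(shape, center, r_outer, r_inner):
    """Boolean spherical shell r_inner <= r <= r_outer."""
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return (d2 <= r_outer**2) & (d2 >= r_inner**2)


def make_ball(shape, center, radius):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    d2 = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2
    return d2 <= radius**2


def make_tube_x(shape, cy, cz, radius, x0, x1):
    """Solid tube along x."""
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - cz) ** 2 + (yy - cy) ** 2 <= radius**2) & (xx >= x0) & (xx <= x1)


def single_seed_set(mask: SparseMask, pos, radius=3.0) -> SeedSet:
    """A one-voxel seed instance at ``pos`` (voxel coords, isotropic 1 um)."""
    pos = tuple(int(p) for p in pos)
    arr = np.array([pos])
    inst = SeedInstance(1, arr, arr, tuple(float(p) for p in pos), radius)
    return SeedSet([inst], mask.domain_shape, mask.voxel_size)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_mask(rng, shape, density=0.2) -> np.ndarray:
    return rng.random(shape) < density


def random_connected_mask(rng, shape, density=0.35) -> np.ndarray:
    """Largest 26-connected component of a random mask (guaranteed non-empty)."""
    from scipy import ndimage

    while True:
        m = rng.random(shape) < density
        if not m.any():
            continue
        lab, n = ndimage.label(m, structure=np.ones((3, 3, 3), bool))
        sizes = np.bincount(lab.ravel())
        sizes[0] = 0
        keep = sizes.argmax()
        out = lab == keep
        if out.sum() >= 5:
            return out
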