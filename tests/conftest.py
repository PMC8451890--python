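import numpy as np
import pytest

from airwaymorph.phantom import TreeSpec, build_tree, rasterize_tree
from airwaymorph.volume import BinaryMask


@pytest.fixture(scope="session")
def small_tree():
    """Complete 4-generation tree: 15 branches, cheap to rasterize."""
    return build_tree(TreeSpec(generations=4, seed=7))


@pytest.fixture(scope="session")
def small_mask(small_tree):
    return rasterize_tree(small_tree, 40.0)


def make_cylinder(diameter_vox: float, length_vox: int, spacing: float = 10.0,
                  axis: int = 2, pad: int = 6) -> BinaryMask:
    """Straight voxel cylinder along ``axis`` with flat end caps."""
    r = diameter_vox / 2.0
    side = int(np.ceil(diameter_vox)) + 2 * pad + 1
    # centre on a voxel: parallel thinning degenerates on exactly
    # even-symmetric tubes whose medial axis falls between voxels
    shape = [side, side, side]
    shape[axis] = length_vox
    idx = np.indices(shape, dtype=float)
    trans = [i for i in range(3) if i != axis]
    c = float(side // 2)
    rad = np.hypot(idx[trans[0]] - c, idx[trans[1]] - c)
    return BinaryMask(values=rad <= r, spacing=spacing)


@pytest.fixture(scope="session")
def cylinder_mask():
    return make_cylinder(diameter_vox=20, length_vox=80)


@pytest.fixture(scope="session")
def y_tube_mask():
    """Two tubes of radius 4 branching at ~60 degrees from a parent tube."""
    shape = (80, 100, 40)
    idx = np.indices(shape, dtype=float).reshape(3, -1).T
    segs = [
        (np.array([40.0, 5.0, 20.0]), np.array([40.0, 50.0, 20.0]), 6.0),
        (np.array([40.0, 50.0, 20.0]), np.array([15.0, 90.0, 20.0]), 4.5),
        (np.array([40.0, 50.0, 20.0]), np.array([65.0, 90.0, 20.0]), 4.5),
    ]
    values = np.zeros(shape, bool)
    for a, b, r in segs:
        ab = b - a
        t = np.clip((idx - a) @ ab / (ab @ ab), 0.0, 1.0)
        d = np.linalg.norm(idx - (a + t[:, None] * ab), axis=1)
        values |= (d <= r).reshape(shape)
    return BinaryMask(values=values, spacing=25.0)
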