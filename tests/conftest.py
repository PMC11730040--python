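import numpy as np
import pytest

import cmbchar as c


@pytest.fixture(scope="session")
def phantom_spec():
    return c.PhantomSpec(seed=7)


@pytest.fixture(scope="session")
def phantom_atlas(phantom_spec):
    """Probability maps plus ground-truth MARS atlas on the default 64^3 grid."""
    probmaps, atlas = c.make_atlas_phantom(phantom_spec)
    return probmaps, atlas


@pytest.fixture(scope="session")
def phantom_lesions(phantom_spec):
    """Default 13-lesion mask (one lesion per structure) and its truth table."""
    return c.make_lesion_mask(phantom_spec)


def binary_grid(data, voxel_dims=(1.0, 1.0, 1.0)):
    data = np.asarray(data, dtype=np.uint8)
    return c.VolumeGrid(data, voxel_dims, c.default_affine(voxel_dims), "binary")


def mask_from_voxels(voxels, shape=(10, 10, 10), voxel_dims=(1.0, 1.0, 1.0)):
    data = np.zeros(shape, dtype=np.uint8)
    for v in voxels:
        data[tuple(v)] = 1
    return binary_grid(data, voxel_dims)


def digitised_ball(radius_voxels, centre=None, shape=None, voxel_dims=(1.0, 1.0, 1.0)):
    """Voxels whose centres lie within ``radius`` (mm) of the centre."""
    if shape is None:
        n = int(2 * radius_voxels / min(voxel_dims)) + 7
        shape = (n, n, n)
    if centre is None:
        centre = tuple((s - 1) / 2 for s in shape)
    idx = np.indices(shape, dtype=float)
    dims = np.asarray(voxel_dims).reshape(3, 1, 1, 1)
    ctr = np.asarray(centre, dtype=float).reshape(3, 1, 1, 1)
    d2 = (((idx - ctr) * dims) ** 2).sum(axis=0)
    return binary_grid((d2 <= radius_voxels**2).astype(np.uint8), voxel_dims)
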