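import dataclasses

import numpy as np
import pytest

from lesionometry.core import Bundle, VoxelGrid
from lesionometry.phantom import (
    BundleDescriptor,
    LesionDescriptor,
    PhantomSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def unit_grid():
    """20^3 grid at 1 mm isotropic."""
    return VoxelGrid.isotropic((20, 20, 20), 1.0)


@pytest.fixture
def small_spec():
    """Compact phantom: one straight tube bundle plus a central spherical lesion."""
    return PhantomSpec(
        shape=(20, 20, 20),
        voxel_size=2.0,
        bundles={
            "tube": BundleDescriptor(
                control_points=((4.0, 19.0, 19.0), (34.0, 19.0, 19.0)),
                radius=3.0,
                n_streamlines=100,
                dispersion=1.0,
            )
        },
        lesions=(LesionDescriptor(center=(19.0, 22.0, 19.0), radii=(4.0, 4.0, 4.0)),),
        seed=7,
    )


def straight_bundle(name="straight", y=10.0, z=10.0, x0=0.0, x1=19.0, n=1):
    """Axis-aligned streamline(s) along x at integer voxel centres of a 1 mm grid."""
    sl = np.column_stack(
        [np.linspace(x0, x1, 40), np.full(40, y), np.full(40, z)]
    )
    return Bundle(name=name, streamlines=[sl.copy() for _ in range(n)])


def brute_force_voxels(streamlines, grid, step):
    """Independent voxelization oracle: pure-python per-point mapping."""
    from lesionometry.phantom import _resample_polyline

    inv = np.linalg.inv(grid.affine)
    out = set()
    for sl in streamlines:
        for p in _resample_polyline(np.asarray(sl, float), step):
            q = inv @ np.array([p[0], p[1], p[2], 1.0])
            idx = tuple(int(round(v)) for v in q[:3])
            if all(0 <= idx[a] < grid.shape[a] for a in range(3)):
                out.add(idx)
    return out
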