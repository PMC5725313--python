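"""Shared fixtures: tiny handcrafted atlases and seeded synthetic worlds."""

import numpy as np
import pytest

from icnengage import GridGeometry, StatMap, SyntheticSpec, ZMapSet, build_atlas
from icnengage.synthetic import make_default_atlas


def simple_geometry(shape=(4, 4, 4), voxel=2.0):
    affine = np.diag([voxel, voxel, voxel, 1.0])
    return GridGeometry(shape=shape, affine=affine)


def random_zmapset(rng, shape=(6, 6, 6), k=4, scale=3.0):
    """Random Gaussian Z volumes: roughly half the voxels supra-threshold."""
    z = rng.normal(loc=2.0, scale=scale, size=(k, *shape))
    return ZMapSet(
        geometry=simple_geometry(shape),
        z=z,
        component_names=[f"C{i+1}" for i in range(k)],
    )


def random_statmap(rng, geometry, p_active=0.4, with_nan=True):
    """Random map: mix of zeros, NaN and positive/negative values."""
    v = rng.normal(loc=3.0, scale=2.0, size=geometry.shape)
    v[rng.random(geometry.shape) > p_active] = 0.0
    if with_nan:
        v[rng.random(geometry.shape) < 0.1] = np.nan
    return StatMap(geometry=geometry, values=v, stat_kind="Z")


@pytest.fixture(scope="session")
def small_spec():
    """Small synthetic world used where the full default would be slow."""
    return SyntheticSpec(
        shape=(16, 16, 16), n_components=5, blob_radius_vox=2.5,
        smooth_fwhm_vox=1.5, seed=0,
    )


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return make_default_atlas(small_spec)


@pytest.fixture(scope="session")
def default_atlas():
    return make_default_atlas(SyntheticSpec(seed=0))


@pytest.fixture
def two_component_atlas():
    """Hand-laid 4x4x4 atlas: two disjoint 8-voxel cubes."""
    geom = simple_geometry()
    z = np.zeros((2, 4, 4, 4))
    z[0, :2, :2, :2] = 6.0
    z[1, 2:, 2:, 2:] = 5.0
    zmaps = ZMapSet(geometry=geom, z=z, component_names=["A", "B"])
    return build_atlas(zmaps, 3.0)
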