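import numpy as np
import pytest

from oculoshape.eye_shape import VoxelMask
from oculoshape.synthetic import EllipsoidSpec, FundusSceneSpec, make_ellipsoid_mask, make_fundus_scene


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def unit_sphere_mask():
    """Noise-free voxelized sphere, r = 12 mm, isotropic 1 mm spacing."""
    mask, spec = make_ellipsoid_mask(EllipsoidSpec(a=12, b=12, c=12, spacing=(1, 1, 1)))
    return mask, spec


@pytest.fixture
def rotated_ellipsoid_mask():
    spec = EllipsoidSpec(a=10, b=12, c=11, rotation=(0, 0, 30), spacing=(1, 1, 1))
    mask, _ = make_ellipsoid_mask(spec)
    return mask, spec


@pytest.fixture
def block_mask():
    """10x10x10 solid block inside a larger grid, 1 mm spacing."""
    grid = np.zeros((14, 14, 14), dtype=bool)
    grid[2:12, 2:12, 2:12] = True
    return VoxelMask(grid=grid, spacing=(1, 1, 1))


@pytest.fixture
def default_scene():
    scene, truth = make_fundus_scene(FundusSceneSpec(), seed=7)
    return scene, truth
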