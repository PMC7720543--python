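import numpy as np
import pytest

from bcadepth import FeatureExtractor, PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def default_truth():
    """The default phantom (invasion 1.5 mm on a 3 mm wall)."""
    return make_phantom(PhantomSpec(seed=7))


@pytest.fixture(scope="session")
def second_truth():
    """An independent phantom for held-out evaluation."""
    return make_phantom(PhantomSpec(seed=8))


@pytest.fixture(scope="session")
def extractor():
    return FeatureExtractor()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def sphere_geometry(r_inner=10.0, r_outer=13.0, pad=4):
    """Voxelized concentric spherical shell on a 1 mm grid."""
    from bcadepth import Mask
    from bcadepth.thickness import geometry_from_regions

    n = int(2 * (r_outer + pad))
    shape = (n, n, n)
    c = (np.asarray(shape) - 1) / 2
    idx = np.indices(shape).astype(float)
    r = np.sqrt(((idx - c[:, None, None, None]) ** 2).sum(0))
    lumen = r < r_inner
    wall = (r >= r_inner) & (r < r_outer)
    like = Mask.from_bool(wall)
    return geometry_from_regions(wall, lumen, like), r


def slab_geometry(width_vox=5, ny=16, nz=16):
    """Planar wall of ``width_vox`` one-mm layers."""
    from bcadepth import Mask
    from bcadepth.thickness import geometry_from_regions

    shape = (width_vox + 7, ny, nz)
    wall = np.zeros(shape, bool)
    wall[3:3 + width_vox] = True
    lumen = np.zeros(shape, bool)
    lumen[:3] = True
    return geometry_from_regions(wall, lumen, Mask.from_bool(wall))
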