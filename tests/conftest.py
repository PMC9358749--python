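import numpy as np
import pytest

from surfmorph import PhantomSpec, phantom
from surfmorph.mesh import uv_sphere


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale phantom: full radius, shortened shaft (keeps volumes small)."""
    return PhantomSpec(shaft_length=60.0, mesh_resolution=1.2, seed=1)


@pytest.fixture(scope="session")
def small_mesh(small_spec):
    return phantom.generate_phantom_mesh(small_spec)


@pytest.fixture(scope="session")
def sphere10():
    return uv_sphere(radius=10.0, n_lat=32, n_lon=64)


@pytest.fixture(scope="session")
def small_volume(small_spec, small_mesh):
    """Noiseless CT-like volume of the small phantom at 0.625 mm voxels."""
    return phantom.voxelize_phantom(
        small_mesh, voxel_size=0.625, psf_sigma=0.4, noise_sd=0.0, seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
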