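import numpy as np
import pytest

from mtubesim import FixtureSpec, fixtures, geometry


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec()


@pytest.fixture(scope="session")
def cell_geometry(default_spec):
    """The default synthetic cell geometry (~38 x 28 µm, 6 slices)."""
    return fixtures.make_geometry(default_spec)


@pytest.fixture(scope="session")
def open_geometry():
    """A large unconstraining geometry: growth behaves as in free space."""
    nz, ny, nx = 60, 70, 70
    cell = np.ones((nz, ny, nx), dtype=bool)
    nucleus = np.zeros_like(cell)
    nucleus[:2, :2, :2] = True  # tiny corner nucleus, far from the centrosome
    cell3d = geometry.Mask3D(cell, pixel_size_um=0.5, z_step_um=0.5)
    nuc3d = geometry.Mask3D(nucleus, pixel_size_um=0.5, z_step_um=0.5)
    return geometry.assemble_geometry(cell3d, nuc3d, (nx // 2, ny // 2, nz // 2))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
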