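import numpy as np
import pytest

from brachymc.materials import material_library
from brachymc.rng import RandomStream
from brachymc.source import (
    EmissionLine,
    PhotonSpectrum,
    SourceGeometry,
    build_gmp_source,
    load_spectrum,
)
from brachymc.transport import VoxelPhantom


@pytest.fixture(scope="session")
def library():
    return material_library()


@pytest.fixture(scope="session")
def spectrum():
    return load_spectrum("ir192-nndc")


@pytest.fixture(scope="session")
def gmp():
    return build_gmp_source()


@pytest.fixture
def rng():
    return RandomStream(12345)


@pytest.fixture(scope="session")
def mono_300kev():
    """A single 300 keV line (closed-form oracles)."""
    return PhotonSpectrum((EmissionLine(0.3, 1.0),))


@pytest.fixture(scope="session")
def point_geometry():
    """A degenerate, effectively transparent source: emission from a
    ~10 nm core with vanishing encapsulation, i.e. a point source."""
    return SourceGeometry(
        core_length=2e-6, core_diameter=1e-6,
        capsule_outer_diameter=2e-6, capsule_inner_diameter=1.5e-6,
        wire_length=1e-6, wire_diameter=1e-6,
        tip_height=1e-6, tip_end_radius=1e-7)


def water_cube(library, n: int) -> VoxelPhantom:
    """A uniform water cube of n^3 1 mm voxels centred on the origin."""
    return VoxelPhantom(
        shape=(n, n, n), spacing_mm=(1.0, 1.0, 1.0),
        origin_cm=(-n / 20.0, -n / 20.0, -n / 20.0),
        material_index=np.zeros((n, n, n), dtype=np.int16),
        materials=[library["water"]])


@pytest.fixture
def water_cube_101(library):
    return water_cube(library, 101)
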