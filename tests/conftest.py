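import numpy as np
import pytest

from mmwi.cohort import (
    BAND1,
    BAND2,
    DERMIS,
    FAT,
    DebyeMedium,
    FrequencyGrid,
    LesionRegion,
    ScanGeometry,
    SkinPhantom,
)


@pytest.fixture(scope="session")
def small_grids():
    """Coarse sub-band grids used to keep simulation-heavy tests fast."""
    return (
        FrequencyGrid(BAND1.start_ghz, BAND1.stop_ghz, 32),
        FrequencyGrid(BAND2.start_ghz, BAND2.stop_ghz, 32),
    )


@pytest.fixture
def geometry():
    return ScanGeometry()


@pytest.fixture
def lossless_medium():
    return DebyeMedium(9.0, 0.0, 1.0, 0.0, name="lossless")


@pytest.fixture
def lesion_phantom(geometry):
    lesion = LesionRegion(
        center_mm=geometry.aperture_center,
        radius_mm=3.0,
        depth_mm=1.0,
        medium=DebyeMedium(4.0, 40.0, 7.2, 0.3, name="lesion"),
    )
    return SkinPhantom(
        layers=[(DERMIS, 1.5), (FAT, None)],
        lesion=lesion,
        label="malignant",
        subtype="basal_cell_carcinoma",
        site="facial_skin",
    )


@pytest.fixture
def homogeneous_phantom():
    return SkinPhantom(layers=[(DERMIS, 1.5), (FAT, None)], lesion=None)


def random_cube(rng, nx=8, ny=6, nz=12, dz=0.2):
    from mmwi.reconstruction import ReflectivityCube, VoxelSpec

    spec = VoxelSpec(nx, ny, nz, 1.5, 1.5, dz)
    return ReflectivityCube(rng.random((nx, ny, nz)) + 0.1, spec)
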