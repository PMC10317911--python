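import numpy as np
import pytest

from msot import (ArrayGeometry, ImpulseResponse, ImageGrid,
                  WavelengthGrid, build_system_matrix, load_reference_spectra)
from msot.geometry import time_window_for_grid

ALL_CHROMOPHORES = ["hbo2", "hbr", "h2o", "lipid", "collagen", "melanin"]


@pytest.fixture(scope="session")
def wl14():
    return WavelengthGrid()


@pytest.fixture(scope="session")
def refs14(wl14):
    return load_reference_spectra(ALL_CHROMOPHORES, wl14)


@pytest.fixture(scope="session")
def wl6():
    """Reduced wavelength grid used to keep end-to-end spectral tests fast."""
    return WavelengthGrid((700, 760, 800, 850, 900, 970))


@pytest.fixture(scope="session")
def refs6(wl6):
    return load_reference_spectra(ALL_CHROMOPHORES, wl6)


@pytest.fixture(scope="session")
def small_grid():
    """24x24 pixels, 0.1 mm pitch, centred on the 20 mm focus."""
    return ImageGrid.centered((24, 24), 0.1, (0.0, 20.0))


@pytest.fixture(scope="session")
def small_geometry(small_grid):
    geom = ArrayGeometry(n_elements=48)
    return time_window_for_grid(geom, small_grid.pixel_centers())


@pytest.fixture(scope="session")
def impulse(small_geometry):
    return ImpulseResponse(sampling_rate_mhz=small_geometry.sampling_rate_mhz)


@pytest.fixture(scope="session")
def small_system(small_geometry, small_grid, impulse):
    return build_system_matrix(small_geometry, small_grid, ir=impulse)


@pytest.fixture(scope="session")
def disc_image(small_grid):
    xx, zz = small_grid.mesh()
    return (xx ** 2 + (zz - 20.0) ** 2 <= 0.35 ** 2).astype(float)


@pytest.fixture(scope="session")
def disc_sinogram(small_system, disc_image):
    return small_system.matvec(disc_image)
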