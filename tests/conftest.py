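import numpy as np
import pytest

import ctdose as cd


@pytest.fixture(scope="session")
def geometry():
    return cd.PhantomGeometry()


@pytest.fixture(scope="session")
def tissue():
    return cd.TissueModel()


@pytest.fixture(scope="session")
def chest_slice_256():
    return cd.make_chest_slice(matrix=256, fov_mm=350)


@pytest.fixture(scope="session")
def chest_slice_128():
    return cd.make_chest_slice(matrix=128, fov_mm=360)


@pytest.fixture(scope="session")
def rois():
    return cd.default_rois()


@pytest.fixture(scope="session")
def water_disc_256():
    """Water-density disc (0 HU) of radius 120 mm in air, 256 matrix."""
    n, fov = 256, 350.0
    sp = fov / n
    c = (np.arange(n) - (n - 1) / 2) * sp
    xx, yy = np.meshgrid(c, c)
    pixels = np.where(xx**2 + yy**2 < 120.0**2, 0.0, -1000.0)
    return cd.ImageGrid(pixels, sp)


@pytest.fixture(scope="session")
def tissue_disc_128():
    """Soft-tissue disc (40 HU) of radius 150 mm, 128 matrix — a uniform
    phantom for noise and calibration measurements."""
    n, fov = 128, 360.0
    sp = fov / n
    c = (np.arange(n) - (n - 1) / 2) * sp
    xx, yy = np.meshgrid(c, c)
    pixels = np.where(xx**2 + yy**2 < 150.0**2, 40.0, -1000.0)
    return cd.ImageGrid(pixels, sp)


@pytest.fixture(scope="session")
def small_series():
    """Compact 2-phase dynamic phantom for pipeline tests."""
    return cd.make_dynamic_series(
        n_phases=2,
        target_lvef=60.0,
        matrix=96,
        fov_mm=360.0,
        slice_thickness_mm=12.0,
        z_margin_mm=2.0,
    )
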