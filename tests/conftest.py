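"""Shared fixtures: small geometries and phantoms sized for fast tests."""

import numpy as np
import pytest

from tiltmar.phantoms import make_pelvis_phantom
from tiltmar.projection import FanBeamGeometry


@pytest.fixture(scope="session")
def small_geom():
    """Coarse fan-beam geometry for unit tests (fast, still full 360)."""
    return FanBeamGeometry(sid_mm=400.0, sdd_mm=1100.0, n_views=180,
                           n_channels=129, fov_radius_mm=120.0)


@pytest.fixture(scope="session")
def pelvis_phantom():
    return make_pelvis_phantom()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disk_image(n: int, pixel_size: float, radius_cm: float, mu: float = 0.2):
    c = (n - 1) / 2
    jj, ii = np.meshgrid(np.arange(n), np.arange(n))
    x = (jj - c) * pixel_size
    y = (c - ii) * pixel_size
    return np.where(x * x + y * y <= radius_cm ** 2, mu, 0.0), x, y


@pytest.fixture(scope="session")
def water_disk_64():
    img, x, y = disk_image(64, 0.3, 5.0)
    return img
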