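import numpy as np
import pytest

from tvmar import Geometry, ImageGrid, make_reference_scenario
from tvmar.simulate import DEFAULT_SEED


@pytest.fixture(scope="session")
def geom64():
    return Geometry.for_image(64, 60)


@pytest.fixture(scope="session")
def ref_sim():
    """Stock desk-scale scenario: 128x128, 90 views, seeded."""
    return make_reference_scenario(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def small_sim():
    """Fast 64x64 / 60-view scenario for unit-level pipeline tests."""
    return make_reference_scenario(seed=5, size=64, n_views=60)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def smooth_phantom():
    """Smooth two-bump phantom supported on the reconstruction circle."""
    n = 128
    geom = Geometry.for_image(n, 180)
    c = (n - 1) / 2
    yy, xx = np.mgrid[0:n, 0:n]
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    vals = np.exp(-r2 / (2 * (n / 6) ** 2)) + 0.5 * np.exp(
        -((xx - c - 15) ** 2 + (yy - c + 10) ** 2) / (2 * (n / 12) ** 2)
    )
    return ImageGrid(vals * geom.circle_mask()), geom
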