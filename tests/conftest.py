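import numpy as np
import pytest

from aortasph import WallGeometry, build_wall
from aortasph.dynamics import StabilizationParams, WallModel


@pytest.fixture(scope="session")
def small_wall():
    """Narrow-sector wall at the reference density (fast, full radial detail)."""
    return build_wall(WallGeometry(sector_deg=15.0, density=0.24))


@pytest.fixture(scope="session")
def small_model(small_wall):
    model = WallModel(small_wall)
    model.homeostatic_reference()
    return model


@pytest.fixture()
def rng():
    return np.random.default_rng(20260921)


def random_F(rng, n=1, spread=0.15):
    """Random in-plane deformation gradients with guaranteed det > 0."""
    F = np.eye(2) + spread * rng.standard_normal((n, 2, 2))
    d = F[:, 0, 0] * F[:, 1, 1] - F[:, 0, 1] * F[:, 1, 0]
    flip = d <= 0.05
    F[flip] = np.eye(2) + 0.05 * rng.standard_normal((flip.sum(), 2, 2))
    return F
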