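import numpy as np
import pytest

from frapmap.sampling import ellipse_mask
from frapmap.sgs import build_grid
from frapmap.variogram import PointSamples, VariogramModel


@pytest.fixture(scope="session")
def cell_grid():
    """35x35 simulation grid on the built-in elliptical cell mask."""
    return build_grid(ellipse_mask(), pixel_size=0.5, target_shape=(35, 35))


@pytest.fixture(scope="session")
def small_grid():
    """Coarser grid for expensive sequential-simulation tests."""
    return build_grid(ellipse_mask(), pixel_size=0.5, target_shape=(20, 20))


@pytest.fixture
def random_points():
    rng = np.random.default_rng(42)
    return PointSamples(u=rng.uniform(0, 50, size=(12, 2)), z=rng.normal(1.5, 0.4, 12))


@pytest.fixture
def exp_model():
    return VariogramModel(a=20.0, b=0.05, c=1.0)
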