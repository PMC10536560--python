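import numpy as np
import pytest

from eqiscope import Grid, GridTransform, ScenarioConfig, generate_scenario

NODATA = -9999.0


def make_grid(values, cell=1000.0, x0=0.0, y0=None, crs="SYNTH:TEST", nodata=NODATA):
    values = np.asarray(values, dtype=np.float64)
    if y0 is None:
        y0 = values.shape[0] * cell
    return Grid(values=values, transform=GridTransform(x0=x0, y0=y0, dx=cell, dy=cell),
                crs=crs, nodata=nodata)


@pytest.fixture
def rng():
    return np.random.default_rng(20160920)


@pytest.fixture(scope="session")
def scenario():
    """Default two-epoch synthetic scenario (shared; treat as read-only)."""
    return generate_scenario(ScenarioConfig(seed=11))


@pytest.fixture(scope="session")
def small_scenario():
    """Fast 80x80 scenario for pipeline smoke tests."""
    return generate_scenario(ScenarioConfig(
        shape=(80, 80), n_zones=4, n_patches=12, seed=5,
        change_regions=(
            __import__("eqiscope").ChangeRegion(10, 25, 10, 25, +0.5),
            __import__("eqiscope").ChangeRegion(50, 65, 50, 65, -0.5),
        )))
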