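import numpy as np
import pytest

import ecoclimex as ec


@pytest.fixture(scope="session")
def params():
    return ec.default_parameters()


@pytest.fixture(scope="session")
def desk_grid():
    """Default 20 x 15 synthetic alpine grid (seed 0)."""
    return ec.make_synthetic_grid(ec.SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def desk_result(desk_grid):
    return ec.run_grid(desk_grid)


@pytest.fixture()
def benign_weekly():
    """A mild 52-week series: warm summers, no stress, saturated air."""
    w = np.arange(52)
    tavg = 12.0 + 8.0 * np.cos(2 * np.pi * (w - 27) / 52)
    return ec.WeeklyClimate(
        tmin=tavg - 3.0,
        tmax=tavg + 3.0,
        rain=np.full(52, 15.0),
        rh09=np.full(52, 100.0),
        rh15=np.full(52, 100.0),
        daylength=ec.day_length(47.0),
    )
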