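import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

import propagule as pg
from propagule import ibm, synthdata


@pytest.fixture(scope="session")
def smoke_grid():
    """1 km × 1 km arena at 10 m spacing."""
    return pg.build_grid(1000, 1000, 10)


@pytest.fixture(scope="session")
def packed_land(smoke_grid):
    return pg.generate_landscape("packed", smoke_grid, seed=21)


@pytest.fixture(scope="session")
def fragmented_land():
    grid = pg.build_grid(2000, 2000, 10)
    return pg.generate_landscape("fragmented", grid, seed=22)


@pytest.fixture(scope="session")
def rainfall_3y():
    """Covers introductions up to day 730 plus a 3-year run."""
    return pg.generate_rainfall(730 + 3 * 365 + 5, seed=12)


@pytest.fixture()
def params():
    return ibm.IbmParams()


@pytest.fixture(scope="session")
def seasonal_truth():
    """A strong seasonal signal peaking mid-February on the logit scale."""
    return synthdata.TruthParams(beta0=-2.0, beta_ps=0.25, beta_se=-1.0,
                                 amplitude=1.5, phase_day=45.0)


@pytest.fixture(scope="session")
def seasonal_table(seasonal_truth):
    return synthdata.generate_outcomes(seasonal_truth, 18000, seed=1)


@pytest.fixture(scope="session")
def seasonal_window_series(seasonal_table):
    from propagule import glm
    return glm.running_window_fit(seasonal_table, "bglm3")
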