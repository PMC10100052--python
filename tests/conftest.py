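import numpy as np
import pandas as pd
import pytest

from settlemate import (
    ChoiceEvent,
    GridRaster,
    SimulationConfig,
    Window,
    make_scene,
)


@pytest.fixture(scope="session")
def small_config():
    """A compact site so scene generation stays fast in unit tests."""
    return SimulationConfig(
        seed=42,
        window=(500.0, 500.0),
        hotspot_count=3,
        nests_per_year=10.0,
        expected_males=12.0,
        n_females=20,
    )


@pytest.fixture(scope="session")
def small_scene(small_config):
    return make_scene(small_config)


@pytest.fixture
def window():
    return Window(0.0, 0.0, 1000.0, 1000.0)


@pytest.fixture
def flat_raster(window):
    return GridRaster(0.0, 0.0, 10.0, np.full((100, 100), 2.5))


@pytest.fixture
def five_male_event():
    """A fixed five-candidate choice scene with distinct H and C."""
    return ChoiceEvent(
        female_id="F1",
        site="S1",
        decision_date="2017-05-10",
        male_ids=[f"M{i}" for i in range(1, 6)],
        xy=np.array([[100.0, 100], [200, 100], [300, 300], [400, 150], [120, 400]]),
        H=np.array([4.0, 2.0, 1.0, 3.0, 5.0]),
        C=np.array([1.2, 1.5, 0.4, 0.9, 0.6]),
        chosen=0,
    )


@pytest.fixture
def nests_table():
    rng = np.random.default_rng(7)
    n = 30
    return pd.DataFrame(
        {
            "site": ["EW"] * 20 + ["LB"] * 10,
            "year": [2017] * 10 + [2018] * 10 + [2017] * 10,
            "x": rng.uniform(100, 900, n),
            "y": rng.uniform(100, 900, n),
        }
    )
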