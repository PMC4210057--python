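import datetime as dt

import pytest

from ads_star.exposure_calendar import label_periods, load_event_fixture
from ads_star.star_model import ModelSpec, build_design
from ads_star.synthetic_data import SimConfig, generate_panel


@pytest.fixture(scope="session")
def events():
    return load_event_fixture()


@pytest.fixture(scope="session")
def study_calendar(events):
    return label_periods(dt.date(2002, 1, 1), dt.date(2007, 12, 31), events)


@pytest.fixture(scope="session")
def small_sim():
    """One-year, 8-district panel with default effect sizes."""
    cfg = SimConfig(
        seed=20, n_districts=8, start=dt.date(2002, 1, 1), end=dt.date(2002, 12, 31)
    )
    panel, truth, graph = generate_panel(cfg)
    return panel, truth, graph


@pytest.fixture(scope="session")
def small_spec():
    return ModelSpec(pollutants=("NOx", "O3"), time_n_basis=8, temp_n_basis=8)


@pytest.fixture(scope="session")
def small_design(small_sim, small_spec):
    panel, truth, graph = small_sim
    return build_design(panel, truth.calendar, graph, small_spec)
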