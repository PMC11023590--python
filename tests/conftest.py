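import numpy as np
import pandas as pd
import pytest

from ethos.panel import PanelDataset
from ethos.synthetic import SyntheticConfig, generate_panel
from ethos.aggregation import load_all_tables, load_summary_stats


@pytest.fixture(scope="session")
def tables():
    """The shipped printed coefficient tables, keyed by (table_id, equation)."""
    return load_all_tables()


@pytest.fixture(scope="session")
def summary_stats():
    return load_summary_stats()


@pytest.fixture(scope="session")
def small_panel():
    """A small but estimable synthetic panel with its true parameters."""
    cfg = SyntheticConfig(n_countries=40, n_years=15, seed=7)
    return generate_panel(cfg)


def make_panel(records: dict) -> PanelDataset:
    """Build a panel from {country: {year: {var: value}}} nested dicts."""
    rows = []
    for country, by_year in records.items():
        for year, values in by_year.items():
            rows.append({"country": country, "year": year, **values})
    return PanelDataset(pd.DataFrame(rows))


@pytest.fixture
def linear_panel():
    """Three countries, exactly linear series, handy for interpolation checks."""
    rows = []
    for c, (a, b) in {"A": (10.0, 2.0), "B": (5.0, -0.5), "C": (0.0, 1.0)}.items():
        for t, year in enumerate(range(2000, 2011)):
            rows.append({"country": c, "year": year, "X": a + b * t,
                         "Y": 1.0 + 0.25 * t})
    return PanelDataset(pd.DataFrame(rows))
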