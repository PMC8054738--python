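import numpy as np
import pandas as pd
import pytest

from cavemon import SimulationConfig, SurveyTable, simulate_dataset


def make_survey_frame(rows):
    """rows: (cave, taxon, date, season, count) tuples."""
    return pd.DataFrame(rows, columns=["cave_id", "taxon_id", "date", "season", "count"])


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated monitoring dataset shared across tests."""
    cfg = SimulationConfig(n_caves=15, n_taxa=5, n_years=4, seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return small_dataset[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def one_unit_table(t_dry, y_dry, t_rainy, y_rainy, start_year=2015):
    """Build a single cave x taxon SurveyTable from decimal-year points."""
    rows = []
    for t, y in zip(t_dry, y_dry):
        date = pd.Timestamp(f"{start_year}-01-01") + pd.Timedelta(days=round(t * 365.25))
        rows.append(("A", "X", date, "dry", int(y)))
    for t, y in zip(t_rainy, y_rainy):
        date = pd.Timestamp(f"{start_year}-01-01") + pd.Timedelta(days=round(t * 365.25))
        rows.append(("A", "X", date, "rainy", int(y)))
    return SurveyTable.from_frame(make_survey_frame(rows))
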