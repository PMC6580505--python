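import pandas as pd
import pytest

from gulotherm import RawSeries, SimConfig, simulate_cohort
from gulotherm.synthetic import cohort_daily_summaries as cohort_daily


def tb_series(cohort, animal_id: str) -> RawSeries:
    grp = cohort.tb[cohort.tb["animal_id"] == animal_id]
    return RawSeries(animal_id, "tb", pd.DatetimeIndex(grp["timestamp"]),
                     grp["tb_c"].to_numpy())


def activity_series(cohort, animal_id: str) -> RawSeries:
    grp = cohort.activity[cohort.activity["animal_id"] == animal_id]
    return RawSeries(animal_id, "activity",
                     pd.DatetimeIndex(grp["timestamp"]),
                     grp["act_total"].to_numpy(dtype=float))


@pytest.fixture(scope="session")
def small_cohort():
    """4 animals, 1 year, half pregnant on average; the workhorse fixture."""
    return simulate_cohort(SimConfig(n_animals=4, years=1, seed=42,
                                     pregnancy_fraction=0.5))


@pytest.fixture(scope="session")
def small_daily(small_cohort):
    return cohort_daily(small_cohort)


@pytest.fixture(scope="session")
def clean_animal():
    """One animal-year with no pregnancy, fevers or artifacts: the pure
    signal + noise model."""
    cfg = SimConfig(n_animals=1, years=1, seed=7, pregnancy_fraction=0.0,
                    fever_rate=0.0, artifact_rate=0.0)
    return simulate_cohort(cfg)
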