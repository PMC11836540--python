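import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from lingcast import schedules, synthetic_data
from lingcast.formats_io import CENSUS_AGE_LOS, CensusCountTable, MortalitySchedule

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def lifetable() -> MortalitySchedule:
    return schedules.load_default_lifetable()


@pytest.fixture(scope="session")
def fertility():
    return schedules.load_default_fertility()


@pytest.fixture(scope="session")
def presets():
    return synthetic_data.scenario_presets()


def zero_mortality_schedule(periods=range(1976, 2101, 5), group="default") -> MortalitySchedule:
    """q ≡ 0 below the maximum age (the 95–99 interval is still closed at 1)."""
    return constant_q_schedule(0.0, periods=periods, group=group)


def constant_q_schedule(q: float, periods=range(1976, 2101, 5), group="default") -> MortalitySchedule:
    rows = [
        (group, p, age, 1.0 if age == 95 else q)
        for p in periods
        for age in range(0, 100, 5)
    ]
    frame = pd.DataFrame(rows, columns=["pop_group", "period_start", "age_lo", "q5"])
    return MortalitySchedule(frame)


def counts_table(per_language: dict[str, dict[tuple[int, int], int]]) -> CensusCountTable:
    """Build a census table from sparse {(year, age_lo): count}, zero-padded."""
    rows = []
    for lang, cells in per_language.items():
        years = sorted({y for (y, _) in cells})
        for year in years:
            for age in CENSUS_AGE_LOS:
                rows.append((lang, year, age, cells.get((year, age), 0)))
    frame = pd.DataFrame(rows, columns=["language", "census_year", "age_lo", "count"])
    return CensusCountTable(frame)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(20240901))
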