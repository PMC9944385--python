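from datetime import date

import pytest

from ddepi import SimulationConfig, simulate_cohort, simulate_diagnosed_cohort
from ddepi.lifetable import packaged_life_table


@pytest.fixture(scope="session")
def life_table():
    return packaged_life_table()


@pytest.fixture(scope="session")
def clean_cohort(life_table):
    """4,000-subject defect-free simulated cohort (subjects, events, truth)."""
    cfg = SimulationConfig(n_subjects=4000, seed=11)
    return simulate_cohort(cfg, life_table) + (cfg,)


@pytest.fixture(scope="session")
def diagnosed_records():
    """5,000 already-diagnosed subjects with known surgery-model truth."""
    return simulate_diagnosed_cohort(5000, seed=5)


STUDY_START = date(1995, 1, 1)
STUDY_END = date(2013, 12, 31)


@pytest.fixture(scope="session")
def study_window():
    return STUDY_START, STUDY_END
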