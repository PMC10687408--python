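import numpy as np
import pandas as pd
import pytest

from milkpersist.pipeline import run_pipeline
from milkpersist.simulate import SimulationConfig, simulate_population


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort():
    """A small multi-herd cohort shared by pipeline-level tests."""
    config = SimulationConfig(n_herds=3, cows_per_herd=40, years=3, seed=7)
    visits, cows, truth = simulate_population(config)
    return config, visits, cows, truth


@pytest.fixture(scope="session")
def small_pipeline(small_cohort):
    _, visits, cows, truth = small_cohort
    result = run_pipeline(visits, cows, seed=7)
    return result, truth


def toy_visits(
    gaps_h,
    yields,
    calving="2021-03-01",
    start_offset_h=6.0,
    lactation_key="cow1_p1",
):
    """Visit table for one lactation from inter-visit gaps (hours)."""
    calving = pd.Timestamp(calving)
    times = calving + pd.to_timedelta(
        start_offset_h + np.cumsum(np.asarray(gaps_h, dtype=float)), unit="h"
    )
    return pd.DataFrame(
        {
            "lactation_key": lactation_key,
            "visit_datetime": times,
            "yield_kg": np.asarray(yields, dtype=float),
        }
    )
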