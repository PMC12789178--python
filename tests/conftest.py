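import datetime as dt

import numpy as np
import pandas as pd
import pytest

from chronest import (
    SimulationConfig,
    gen_ambient_trace,
    gen_nest_temperature,
    gen_onset_table,
    gen_population,
    standardise_onsets,
)


@pytest.fixture(scope="session")
def small_sim():
    """A small two-year population shared across read-only tests."""
    cfg = SimulationConfig(seed=42, n_females=50, n_years=2, onsets_per_female=6)
    truth, broods = gen_population(cfg)
    onsets = gen_onset_table(cfg, truth)
    return cfg, truth, broods, onsets


@pytest.fixture(scope="session")
def small_std(small_sim):
    _, _, _, onsets = small_sim
    std, _ = standardise_onsets(onsets)
    return std


@pytest.fixture()
def one_day_trace():
    """A 3-day trace with one programmed 12-min off-bout at 05:30."""
    cfg = SimulationConfig(seed=9)
    ambient = gen_ambient_trace(4, seed=9, start=dt.date(2021, 4, 10))
    sched = {
        dt.date(2021, 4, 12): [(5.5, 12.0), (9.0, 15.0)],
    }
    trace = gen_nest_temperature(
        sched, ambient, cfg, incubation_start=dt.date(2021, 4, 11)
    )
    return cfg, trace


def make_trace(temp, amb=None, start="2021-04-12", step_min=3, accuracy=0.0625):
    """Build a TemperatureTrace from raw arrays for unit tests."""
    from chronest.bout_detect import TemperatureTrace

    temp = np.asarray(temp, dtype=float)
    times = pd.date_range(start, periods=len(temp), freq=f"{step_min}min")
    if amb is None:
        amb = np.full(len(temp), 10.0)
    return TemperatureTrace("T", times, temp, accuracy, np.asarray(amb, dtype=float))
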