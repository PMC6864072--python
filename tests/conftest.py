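import datetime as dt
import os

# single-threaded numerics: keeps the suite reproducible and avoids BLAS/OpenMP
# oversubscription (must be set before numpy is first imported)
for _var in ("OMP_NUM_THREADS", "OPENBLAS_NUM_THREADS", "MKL_NUM_THREADS"):
    os.environ.setdefault(_var, "1")

import numpy as np
import pytest

from phytoep.synth import (EphemerisTable, IrrigationSchedule, SimulationConfig,
                           simulate_traces)

DAY = 86400.0


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """Two quiet days of one plant: fast and noise-free."""
    return SimulationConfig(n_plants=1, duration_days=2.0, noise_sd=0.0,
                            baseline_sd_between_plants=0.0, seed=7)


@pytest.fixture
def small_noisy_config():
    return SimulationConfig(n_plants=2, duration_days=2.0, seed=7)


@pytest.fixture
def deficit_schedule():
    """Full irrigation for day 0, then a 2-day total cutoff, then rewatered."""
    origin = dt.datetime(2018, 6, 1)
    return IrrigationSchedule.from_spans(
        [(0.0, 1 * DAY, 1.0), (1 * DAY, 3 * DAY, 0.0), (3 * DAY, 4 * DAY, 1.0)],
        origin=origin)


@pytest.fixture
def ephemeris():
    return EphemerisTable.constant(dt.date(2018, 6, 1), 6, sunrise=6.0, sunset=20.0)


@pytest.fixture
def quiet_trace(small_config):
    return simulate_traces(small_config)[0]
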