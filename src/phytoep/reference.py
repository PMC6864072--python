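"""Reference study conditions for the synthetic experiment.

A two-week, five-plant greenhouse run at the desk-scale 4 Hz rate with a
single drought episode: optimal irrigation for four days, a 50 % deficit for
two days, a 36-hour irrigation cutoff, then rewatering and recovery.  The
diel amplitude is 7.5x the measurement-noise standard deviation.  These
conditions drive the parameter-recovery and qualitative-reproduction checks
and the worked example in the README.
"""

from __future__ import annotations

import datetime as _dt

from .classify import PipelineConfig
from .synth import EphemerisTable, IrrigationSchedule, SimulationConfig

__all__ = [
    "reference_config",
    "reference_schedule",
    "reference_ephemeris",
    "reference_pipeline_config",
    "quickstart_pipeline_config",
    "REFERENCE_SPANS",
]

_DAY = 86400.0

#: optimal (4 d) -> 50 % deficit (2 d) -> cutoff (36 h) -> rewatered
REFERENCE_SPANS = (
    (0.0, 4 * _DAY, 1.0),
    (4 * _DAY, 6 * _DAY, 0.5),
    (6 * _DAY, 7.5 * _DAY, 0.0),
    (7.5 * _DAY, 14 * _DAY, 1.0),
)


def reference_config(seed: int = 1) -> SimulationConfig:
    return SimulationConfig(seed=seed)  # defaults are the reference conditions


def reference_schedule(start_time: _dt.datetime | None = None) -> IrrigationSchedule:
    origin = start_time or reference_config().start_time
    return IrrigationSchedule.from_spans(REFERENCE_SPANS, origin=origin)


def reference_ephemeris(config: SimulationConfig | None = None) -> EphemerisTable:
    cfg = config or reference_config()
    n_days = int(cfg.duration_days) + 1
    return EphemerisTable.constant(cfg.start_time.date(), n_days,
                                   cfg.sunrise_hour, cfg.sunset_hour)


def reference_pipeline_config(seed: int = 1) -> PipelineConfig:
    return PipelineConfig(sim=reference_config(seed=seed),
                          schedule_spans=REFERENCE_SPANS, seed=seed)


def quickstart_pipeline_config(seed: int = 1) -> PipelineConfig:
    """A one-plant, three-day run (with a deficit episode) for smoke tests."""
    sim = SimulationConfig(n_plants=1, duration_days=3.0, seed=seed)
    spans = (
        (0.0, 1 * _DAY, 1.0),
        (1 * _DAY, 1.75 * _DAY, 0.5),
        (1.75 * _DAY, 2.25 * _DAY, 0.0),
        (2.25 * _DAY, 3 * _DAY, 1.0),
    )
    return PipelineConfig(sim=sim, schedule_spans=spans, seed=seed)
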