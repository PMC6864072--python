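"""Synthetic plant electrical-potential (EP) recordings.

Generates labelled surrogate voltage traces that reproduce the phenomenology of
greenhouse EP monitoring: a diel (24 h) cycle with a night minimum and an
afternoon maximum, a progressive baseline drop with attenuated daily peaks
under water deficit, a transient downward spike on rewatering, coloured
measurement noise, and between-plant baseline variability.  Every downstream
stage of the pipeline (filtering, feature extraction, labelling, PCA,
classification) can therefore be exercised without any recorded data.

All internal times are seconds since the start of the simulation; timestamps
become ISO-8601 / ``datetime`` objects only at the I/O boundary.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "IrrigationSchedule",
    "EphemerisTable",
    "SignalTrace",
    "ScheduleError",
    "colored_noise",
    "diel_component",
    "simulate_traces",
]

SECONDS_PER_DAY = 86400.0


class ScheduleError(ValueError):
    """Irrigation schedule is malformed (gap, overlap, or missing coverage)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic EP experiment.

    Defaults describe the reference desk-scale study conditions: a two-week,
    five-plant greenhouse run sampled at 4 Hz (the recording hardware runs at
    400 Hz; the rate is configurable), with a 15 mV diel bump over a 20 mV
    baseline and 2 mV of pink measurement noise.
    """

    sample_rate: float = 4.0            # Hz
    duration_days: float = 14.0
    n_plants: int = 5
    start_time: _dt.datetime = _dt.datetime(2018, 6, 1)
    baseline_mv: float = 20.0
    baseline_sd_between_plants: float = 5.0
    diel_amplitude: float = 15.0        # mV, peak height above baseline
    diel_peak_hour: float = 14.0        # solar noon at about 14 h local time
    sunrise_hour: float = 6.0
    sunset_hour: float = 20.0
    dawn_prepeak: bool = False          # optional small bump after sunrise
    dawn_prepeak_fraction: float = 0.3
    drought_drift_mv_per_day: float = 5.0
    drought_attenuation: float = 0.7    # diel amplitude factor per deficit day
    rewatering_spike_mv: float = 10.0   # downward magnitude
    recovery_tau_hours: float = 6.0
    noise_beta: float = 1.0             # PSD ~ f**-beta
    noise_sd: float = 2.0               # mV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.duration_days <= 0:
            raise ValueError("duration must be positive")
        if self.n_plants < 1:
            raise ValueError("need at least one plant")
        if not 0.0 <= self.drought_attenuation <= 1.0:
            raise ValueError("drought_attenuation must lie in [0, 1]")
        if not self.sunrise_hour < self.diel_peak_hour < self.sunset_hour:
            raise ValueError("require sunrise < diel_peak_hour < sunset")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_days * SECONDS_PER_DAY * self.sample_rate))

    @property
    def duration_seconds(self) -> float:
        return self.duration_days * SECONDS_PER_DAY


@dataclass(frozen=True)
class IrrigationSchedule:
    """Stepwise irrigation level (fraction of optimal, in [0, 1]) vs time.

    ``starts`` are segment start times in seconds from the simulation start;
    segments are contiguous by construction and the schedule covers
    ``[starts[0], end)``.  ``origin`` anchors second 0 to an absolute time so
    that labelling by timestamp is possible.
    """

    starts: np.ndarray
    levels: np.ndarray
    end: float
    origin: _dt.datetime | None = None

    def __post_init__(self) -> None:
        starts = np.asarray(self.starts, dtype=float)
        levels = np.asarray(self.levels, dtype=float)
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "levels", levels)
        if starts.ndim != 1 or starts.size == 0 or starts.size != levels.size:
            raise ScheduleError("starts and levels must be equal-length 1-d")
        if starts[0] != 0.0:
            raise ScheduleError("first segment must start at t=0")
        if np.any(np.diff(starts) <= 0):
            raise ScheduleError("segment starts must be strictly increasing")
        if self.end <= starts[-1]:
            raise ScheduleError("schedule end must lie beyond the last segment start")
        if np.any((levels < 0) | (levels > 1)):
            raise ScheduleError("irrigation levels must lie in [0, 1]")

    @classmethod
    def constant(cls, level: float, duration_s: float,
                 origin: _dt.datetime | None = None) -> "IrrigationSchedule":
        return cls(np.array([0.0]), np.array([level]), float(duration_s), origin)

    @classmethod
    def from_spans(cls, spans: Sequence[tuple[float, float, float]],
                   origin: _dt.datetime | None = None) -> "IrrigationSchedule":
        """Build from explicit (start_s, end_s, level) spans; gaps are errors."""
        spans = sorted(spans, key=lambda s: s[0])
        starts, levels = [], []
        for i, (s, e, lvl) in enumerate(spans):
            if e <= s:
                raise ScheduleError(f"span {i} has non-positive length")
            if i > 0:
                prev_end = spans[i - 1][1]
                if s > prev_end:
                    raise ScheduleError(f"gap in irrigation schedule before t={s}")
                if s < prev_end:
                    raise ScheduleError(f"overlapping spans at t={s}")
            starts.append(s)
            levels.append(lvl)
        return cls(np.array(starts), np.array(levels), float(spans[-1][1]), origin)

    def segment_index(self, t: np.ndarray | float) -> np.ndarray:
        return np.clip(np.searchsorted(self.starts, t, side="right") - 1,
                       0, self.starts.size - 1)

    def level_at(self, t: np.ndarray | float) -> np.ndarray:
        """Irrigation level at time(s) ``t`` (seconds from the origin)."""
        return self.levels[self.segment_index(t)]

    def deficit_run_start(self) -> np.ndarray:
        """Per segment: start time of the ongoing contiguous deficit run (NaN if none)."""
        run = np.full(self.starts.size, np.nan)
        for i, lvl in enumerate(self.levels):
            if lvl < 1.0:
                run[i] = run[i - 1] if (i > 0 and self.levels[i - 1] < 1.0) else self.starts[i]
        return run

    def covers(self, duration_s: float) -> bool:
        return self.end >= duration_s

    def seconds_from(self, timestamps) -> np.ndarray:
        if self.origin is None:
            raise ScheduleError("schedule has no absolute origin")
        ts = np.asarray(timestamps, dtype="datetime64[us]")
        origin = np.datetime64(self.origin, "us")
        return (ts - origin) / np.timedelta64(1, "s")


@dataclass(frozen=True)
class EphemerisTable:
    """Per calendar day: sunrise and sunset as hour-of-day."""

    days: dict = field(default_factory=dict)  # date -> (sunrise_h, sunset_h)

    def __post_init__(self) -> None:
        for day, (rise, set_) in self.days.items():
            if not rise < set_:
                raise ValueError(f"sunrise must precede sunset on {day}")

    @classmethod
    def constant(cls, start_date: _dt.date, n_days: int,
                 sunrise: float = 6.0, sunset: float = 20.0) -> "EphemerisTable":
        days = {start_date + _dt.timedelta(days=i): (sunrise, sunset)
                for i in range(n_days)}
        return cls(days)

    def sunrise_sunset(self, date: _dt.date) -> tuple[float, float]:
        try:
            return self.days[date]
        except KeyError:
            raise KeyError(f"ephemeris does not cover {date}") from None

    def covers(self, start: _dt.date, end: _dt.date) -> bool:
        d = start
        while d <= end:
            if d not in self.days:
                return False
            d += _dt.timedelta(days=1)
        return True


@dataclass(frozen=True)
class SignalTrace:
    """A uniformly sampled EP voltage series (mV) for a single plant."""

    plant_id: str
    start_time: _dt.datetime
    sample_rate: float
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if v.ndim != 1:
            raise ValueError("values must be one-dimensional")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration_seconds(self) -> float:
        return self.n / self.sample_rate

    def times_seconds(self) -> np.ndarray:
        return np.arange(self.n) / self.sample_rate

    def timestamps(self) -> np.ndarray:
        start = np.datetime64(self.start_time, "us")
        step = np.timedelta64(int(round(1e6 / self.sample_rate)), "us")
        return start + np.arange(self.n) * step

    def with_values(self, values: np.ndarray, sample_rate: float | None = None,
                    start_time: _dt.datetime | None = None) -> "SignalTrace":
        return replace(self, values=np.asarray(values, dtype=float),
                       sample_rate=sample_rate or self.sample_rate,
                       start_time=start_time or self.start_time)


# ---------------------------------------------------------------------------
# Signal components
# ---------------------------------------------------------------------------


def colored_noise(n: int, beta: float, sd: float,
                  seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Gaussian noise with power spectral density proportional to f**(-beta).

    Spectral-shaping construction: a white Gaussian sequence is transformed to
    the frequency domain, each non-DC bin is multiplied by f**(-beta/2), and
    the result is inverse-transformed and rescaled to standard deviation
    ``sd``.  beta=0 gives white, 1 pink, 2 brown; negative beta gives blue
    (-1) and purple (-2) noise.
    """
    if n < 2:
        raise ValueError("need at least 2 samples of noise")
    if sd < 0:
        raise ValueError("sd must be non-negative")
    if sd == 0:
        return np.zeros(n)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shaping = np.zeros_like(f)
    shaping[1:] = f[1:] ** (-beta / 2.0)
    x = np.fft.irfft(spectrum * shaping, n)
    scale = x.std()
    if scale == 0:
        return np.zeros(n)
    return x * (sd / scale)


def _raised_cosine(hours: np.ndarray, sunrise: np.ndarray, peak: float,
                   sunset: np.ndarray, amplitude: float) -> np.ndarray:
    """Asymmetric raised-cosine bump: 0 at sunrise/sunset, ``amplitude`` at peak.

    The half-cosine rise and fall both have zero slope at their endpoints, so
    the daily profile is flat at night and smooth through the peak.
    """
    h = np.asarray(hours, dtype=float)
    out = np.zeros_like(h)
    rising = (h >= sunrise) & (h < peak)
    falling = (h >= peak) & (h <= sunset)
    rise_span = np.maximum(peak - sunrise, 1e-9)
    fall_span = np.maximum(sunset - peak, 1e-9)
    if np.ndim(sunrise):
        out[rising] = 0.5 * (1 - np.cos(np.pi * (h[rising] - sunrise[rising]) / rise_span[rising]))
        out[falling] = 0.5 * (1 + np.cos(np.pi * (h[falling] - peak) / fall_span[falling]))
    else:
        out[rising] = 0.5 * (1 - np.cos(np.pi * (h[rising] - sunrise) / rise_span))
        out[falling] = 0.5 * (1 + np.cos(np.pi * (h[falling] - peak) / fall_span))
    return amplitude * out


def diel_component(hours_of_day: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Noise-free daily EP cycle evaluated at the given hours of day.

    Zero outside daylight, peaking at ``diel_peak_hour`` with value
    ``diel_amplitude``.  With ``dawn_prepeak`` enabled a smaller transient bump
    is added in the first three hours after sunrise (the early-morning peak
    seen intermittently in real recordings).
    """
    h = np.asarray(hours_of_day, dtype=float)
    out = _raised_cosine(h, config.sunrise_hour, config.diel_peak_hour,
                         config.sunset_hour, config.diel_amplitude)
    if config.dawn_prepeak:
        pre_end = min(config.sunrise_hour + 3.0, config.diel_peak_hour)
        pre_peak = 0.5 * (config.sunrise_hour + pre_end)
        out += _raised_cosine(h, config.sunrise_hour, pre_peak, pre_end,
                              config.dawn_prepeak_fraction * config.diel_amplitude)
    return out


def _stress_state(t: np.ndarray, schedule: IrrigationSchedule,
                  config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Baseline stress offset (mV, <= 0) and deficit exposure (days) at times t.

    During a deficit segment the offset integrates -drought_drift*(1-level)
    per day and the exposure integrates (1-level) per day.  At a transition
    back to full irrigation the offset additionally receives the downward
    rewatering spike; during full irrigation both relax exponentially to zero
    with the recovery time constant.
    """
    tau = config.recovery_tau_hours * 3600.0
    starts = schedule.starts
    levels = schedule.levels
    n_seg = starts.size
    # state at each segment start
    d0 = np.zeros(n_seg)  # drift offset
    e0 = np.zeros(n_seg)  # exposure, days
    for i in range(1, n_seg):
        seg_len = starts[i] - starts[i - 1]
        lvl = levels[i - 1]
        if lvl < 1.0:
            d0[i] = d0[i - 1] - config.drought_drift_mv_per_day * (1 - lvl) * seg_len / SECONDS_PER_DAY
            e0[i] = e0[i - 1] + (1 - lvl) * seg_len / SECONDS_PER_DAY
        else:
            decay = np.exp(-seg_len / tau) if tau > 0 else 0.0
            d0[i] = d0[i - 1] * decay
            e0[i] = e0[i - 1] * decay
        if levels[i] == 1.0 and lvl < 1.0:
            d0[i] -= config.rewatering_spike_mv
    seg = schedule.segment_index(t)
    u = t - starts[seg]
    lvl = levels[seg]
    drift = np.where(
        lvl < 1.0,
        d0[seg] - config.drought_drift_mv_per_day * (1 - lvl) * u / SECONDS_PER_DAY,
        d0[seg] * (np.exp(-u / tau) if tau > 0 else 0.0),
    )
    exposure = np.where(
        lvl < 1.0,
        e0[seg] + (1 - lvl) * u / SECONDS_PER_DAY,
        e0[seg] * (np.exp(-u / tau) if tau > 0 else 0.0),
    )
    return drift, exposure


def simulate_traces(config: SimulationConfig,
                    schedule: IrrigationSchedule | None = None,
                    ephemeris: EphemerisTable | None = None) -> list[SignalTrace]:
    """Simulate one EP trace per plant under the given irrigation regimen.

    EP(t) = plant baseline + stress offset(t)
            + attenuation**exposure(t) * diel(t) + coloured noise,
    with per-plant baselines drawn once from N(baseline, baseline_sd) and the
    stress offset/exposure driven by the schedule (see :func:`_stress_state`).
    Identical config (including seed) yields bit-identical traces.
    """
    duration_s = config.duration_seconds
    if schedule is None:
        schedule = IrrigationSchedule.constant(1.0, duration_s, config.start_time)
    if not schedule.covers(duration_s):
        raise ScheduleError("irrigation schedule does not cover the simulated span")
    n_days = int(np.ceil(config.duration_days))
    start_date = config.start_time.date()
    if ephemeris is None:
        ephemeris = EphemerisTable.constant(start_date, n_days + 1,
                                            config.sunrise_hour, config.sunset_hour)
    end_date = (config.start_time + _dt.timedelta(seconds=duration_s - 1)).date()
    if not ephemeris.covers(start_date, end_date):
        raise ValueError("ephemeris does not cover the simulated span")

    n = config.n_samples
    t = np.arange(n) / config.sample_rate
    midnight = _dt.datetime.combine(start_date, _dt.time())
    start_offset = (config.start_time - midnight).total_seconds()
    abs_sec = start_offset + t
    day_idx = (abs_sec // SECONDS_PER_DAY).astype(np.int64)
    hours = (abs_sec % SECONDS_PER_DAY) / 3600.0

    uniq_days = np.arange(day_idx.max() + 1)
    rises = np.empty(uniq_days.size)
    sets = np.empty(uniq_days.size)
    for i in uniq_days:
        rises[i], sets[i] = ephemeris.sunrise_sunset(start_date + _dt.timedelta(days=int(i)))
    diel = _raised_cosine(hours, rises[day_idx], config.diel_peak_hour,
                          sets[day_idx], config.diel_amplitude)
    if config.dawn_prepeak:
        # pre-peak is only supported with a day-independent sunrise
        pre_end = min(float(rises[0]) + 3.0, config.diel_peak_hour)
        diel += _raised_cosine(hours, float(rises[0]),
                               0.5 * (float(rises[0]) + pre_end), pre_end,
                               config.dawn_prepeak_fraction * config.diel_amplitude)

    drift, exposure = _stress_state(t, schedule, config)
    deterministic = drift + (config.drought_attenuation ** exposure) * diel

    root = np.random.SeedSequence(config.seed)
    base_rng = np.random.default_rng(root.spawn(1)[0])
    baselines = config.baseline_mv + config.baseline_sd_between_plants * \
        base_rng.standard_normal(config.n_plants)
    noise_seeds = root.spawn(config.n_plants + 1)[1:]

    traces = []
    for p in range(config.n_plants):
        if config.noise_sd > 0:
            noise = colored_noise(n, config.noise_beta, config.noise_sd,
                                  np.random.default_rng(noise_seeds[p]))
        else:
            noise = 0.0
        values = baselines[p] + deterministic + noise
        traces.append(SignalTrace(plant_id=f"plant_{p:02d}",
                                  start_time=config.start_time,
                                  sample_rate=config.sample_rate,
                                  values=values))
    logger.info("simulated %d plants x %.1f days at %g Hz (%d samples each)",
                config.n_plants, config.duration_days, config.sample_rate, n)
    return traces
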