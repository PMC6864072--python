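"""Acquisition-chain emulation and daily-cycle analysis.

Implements the recording chain applied to raw EP traces — zero-phase low-pass
and mains notch filtering, decimation to one point per minute — and the
24-hour cycle bookkeeping used for descriptive analysis: midnight-aligned
cycle splitting, per-cycle min-max normalization, and mean +/- s.e.m.
averaging into a daily profile.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

from .synth import SignalTrace

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSpec",
    "DayCycle",
    "DailyProfile",
    "apply_filters",
    "decimate_to_minutes",
    "split_daily_cycles",
    "normalize_cycle",
    "average_cycles",
]

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass + mains band-stop chain of the acquisition hardware."""

    lowpass_cutoff: float = 30.0          # Hz
    notch_freqs: tuple = (50.0, 100.0)    # Hz
    order: int = 4
    notch_q: float = 30.0

    def __post_init__(self) -> None:
        if self.lowpass_cutoff <= 0 or any(f <= 0 for f in self.notch_freqs):
            raise ValueError("filter critical frequencies must be positive")


@dataclass(frozen=True)
class DayCycle:
    """One midnight-to-midnight day of a 1/min trace (exactly 1440 points)."""

    plant_id: str
    day_index: int
    date: _dt.date
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (MINUTES_PER_DAY,):
            raise ValueError(f"a day cycle has exactly {MINUTES_PER_DAY} points")


@dataclass(frozen=True)
class DailyProfile:
    """Pointwise mean and standard error over n aggregated day cycles."""

    mean: np.ndarray
    sem: np.ndarray
    n: int


def apply_filters(trace: SignalTrace, spec: FilterSpec = FilterSpec()) -> SignalTrace:
    """Zero-phase low-pass then notch filtering of a trace.

    Filters whose critical frequency reaches the Nyquist frequency are skipped
    with a logged notice, so desk-scale low-rate traces pass unchanged.
    """
    x = np.asarray(trace.values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("trace contains non-finite values")
    nyquist = trace.sample_rate / 2.0
    if spec.lowpass_cutoff < nyquist:
        sos = _sig.butter(spec.order, spec.lowpass_cutoff, btype="low",
                          fs=trace.sample_rate, output="sos")
        x = _sig.sosfiltfilt(sos, x)
    else:
        logger.info("skipping low-pass at %g Hz (Nyquist %g Hz)",
                    spec.lowpass_cutoff, nyquist)
    for f0 in spec.notch_freqs:
        if f0 < nyquist:
            b, a = _sig.iirnotch(f0, spec.notch_q, fs=trace.sample_rate)
            x = _sig.filtfilt(b, a, x)
        else:
            logger.info("skipping notch at %g Hz (Nyquist %g Hz)", f0, nyquist)
    return trace.with_values(x)


def decimate_to_minutes(trace: SignalTrace) -> SignalTrace:
    """Decimate to one point per minute (mean of the samples in each minute).

    Averaging doubles as the anti-alias step.  A trailing partial minute is
    dropped.  A 24 h trace yields exactly 1440 points regardless of the input
    rate.
    """
    samples_per_minute = trace.sample_rate * 60.0
    if samples_per_minute < 1:
        raise ValueError("trace must have at least one sample per minute")
    n_minutes = int(trace.n / samples_per_minute)
    if n_minutes == 0:
        return trace.with_values(np.empty(0), sample_rate=1 / 60.0)
    idx = (np.arange(trace.n) / samples_per_minute).astype(np.int64)
    keep = idx < n_minutes
    sums = np.bincount(idx[keep], weights=trace.values[keep], minlength=n_minutes)
    counts = np.bincount(idx[keep], minlength=n_minutes)
    return trace.with_values(sums / counts, sample_rate=1 / 60.0)


def split_daily_cycles(trace: SignalTrace) -> list[DayCycle]:
    """Split a 1/min trace into complete civil-midnight-aligned day cycles.

    Partial leading and trailing days are dropped; a trace shorter than one
    full day yields an empty list.
    """
    if not np.isclose(trace.sample_rate, 1 / 60.0):
        raise ValueError("split_daily_cycles expects a one-point-per-minute trace")
    midnight = _dt.datetime.combine(trace.start_time.date(), _dt.time())
    offset_min = int(round((trace.start_time - midnight).total_seconds() / 60.0))
    first = (MINUTES_PER_DAY - offset_min) % MINUTES_PER_DAY
    n_cycles = (trace.n - first) // MINUTES_PER_DAY
    if n_cycles <= 0:
        logger.info("trace %s holds no complete day cycle", trace.plant_id)
        return []
    first_date = (trace.start_time + _dt.timedelta(minutes=first)).date()
    cycles = []
    for d in range(int(n_cycles)):
        lo = first + d * MINUTES_PER_DAY
        cycles.append(DayCycle(plant_id=trace.plant_id, day_index=d,
                               date=first_date + _dt.timedelta(days=d),
                               values=trace.values[lo:lo + MINUTES_PER_DAY]))
    return cycles


def normalize_cycle(cycle: DayCycle) -> DayCycle:
    """Min-max scale one day cycle to [0, 1]; a constant cycle maps to zeros."""
    v = cycle.values
    span = v.max() - v.min()
    if span == 0:
        scaled = np.zeros_like(v)
    else:
        scaled = (v - v.min()) / span
    return DayCycle(cycle.plant_id, cycle.day_index, cycle.date, scaled)


def average_cycles(cycles: list[DayCycle]) -> DailyProfile:
    """Pointwise mean and s.e.m. (sd/sqrt(n), 0 for n=1) across day cycles."""
    if not cycles:
        raise ValueError("need at least one cycle to average")
    stack = np.stack([c.values for c in cycles])
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    return DailyProfile(mean=mean, sem=sem, n=n)
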