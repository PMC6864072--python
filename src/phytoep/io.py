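"""Readers and writers for the pipeline's on-disk formats.

Traces travel as HDF5 (one dataset per plant with plant_id/start_time/rate
attributes) or long-format CSV; schedules and ephemeris tables as CSV with
ISO-8601 timestamps; simulation configs as YAML.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .synth import EphemerisTable, IrrigationSchedule, SignalTrace, SimulationConfig

__all__ = [
    "save_traces_hdf5", "load_traces_hdf5",
    "save_traces_csv", "load_traces_csv",
    "save_schedule_csv", "load_schedule_csv",
    "save_ephemeris_csv", "load_ephemeris_csv",
    "save_config_yaml", "load_config_yaml",
]


def save_traces_hdf5(traces: list[SignalTrace], path: str | Path) -> None:
    with h5py.File(path, "w") as fh:
        for trace in traces:
            ds = fh.create_dataset(trace.plant_id, data=trace.values)
            ds.attrs["plant_id"] = trace.plant_id
            ds.attrs["start_time"] = trace.start_time.isoformat()
            ds.attrs["sample_rate"] = trace.sample_rate


def load_traces_hdf5(path: str | Path) -> list[SignalTrace]:
    traces = []
    with h5py.File(path, "r") as fh:
        for key in sorted(fh.keys()):
            ds = fh[key]
            traces.append(SignalTrace(
                plant_id=str(ds.attrs["plant_id"]),
                start_time=_dt.datetime.fromisoformat(str(ds.attrs["start_time"])),
                sample_rate=float(ds.attrs["sample_rate"]),
                values=ds[...],
            ))
    return traces


def save_traces_csv(traces: list[SignalTrace], path: str | Path) -> None:
    frames = [pd.DataFrame({"plant_id": t.plant_id, "timestamp": t.timestamps(),
                            "mV": t.values}) for t in traces]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_traces_csv(path: str | Path) -> list[SignalTrace]:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    traces = []
    for plant, grp in df.groupby("plant_id", sort=True):
        ts = grp["timestamp"].to_numpy()
        if len(ts) < 2:
            raise ValueError(f"plant {plant!r} has fewer than 2 samples")
        steps = np.diff(ts) / np.timedelta64(1, "s")
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"plant {plant!r} is not uniformly sampled")
        traces.append(SignalTrace(plant_id=str(plant),
                                  start_time=pd.Timestamp(ts[0]).to_pydatetime(),
                                  sample_rate=1.0 / steps[0],
                                  values=grp["mV"].to_numpy(dtype=float)))
    return traces


def save_schedule_csv(schedule: IrrigationSchedule, path: str | Path) -> None:
    if schedule.origin is None:
        raise ValueError("schedule needs an absolute origin to serialise")
    origin = pd.Timestamp(schedule.origin)
    rows = [{"start_time": (origin + pd.Timedelta(seconds=s)).isoformat(),
             "level": lvl} for s, lvl in zip(schedule.starts, schedule.levels)]
    rows.append({"start_time": (origin + pd.Timedelta(seconds=schedule.end)).isoformat(),
                 "level": ""})  # sentinel row marking the schedule end
    pd.DataFrame(rows).to_csv(path, index=False)


def load_schedule_csv(path: str | Path) -> IrrigationSchedule:
    df = pd.read_csv(path)
    times = pd.to_datetime(df["start_time"])
    origin = times.iloc[0].to_pydatetime()
    seconds = (times - times.iloc[0]).dt.total_seconds().to_numpy()
    levels = pd.to_numeric(df["level"], errors="coerce").to_numpy()
    if np.isnan(levels[-1]):  # trailing end-sentinel
        end = float(seconds[-1])
        seconds, levels = seconds[:-1], levels[:-1]
    else:
        end = float(seconds[-1]) + 86400.0
    return IrrigationSchedule(seconds, levels, end, origin)


def save_ephemeris_csv(ephemeris: EphemerisTable, path: str | Path) -> None:
    rows = [{"date": d.isoformat(), "sunrise": rise, "sunset": set_}
            for d, (rise, set_) in sorted(ephemeris.days.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def load_ephemeris_csv(path: str | Path) -> EphemerisTable:
    df = pd.read_csv(path)
    days = {_dt.date.fromisoformat(str(r.date)): (float(r.sunrise), float(r.sunset))
            for r in df.itertuples()}
    return EphemerisTable(days)


def save_config_yaml(config: SimulationConfig, path: str | Path) -> None:
    data = {k: (v.isoformat() if isinstance(v, _dt.datetime) else v)
            for k, v in config.__dict__.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_config_yaml(path: str | Path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text())
    if "start_time" in data:
        data["start_time"] = _dt.datetime.fromisoformat(data["start_time"])
    return SimulationConfig(**data)
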