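"""Normalized, labelled datasets for supervised modelling.

Feature matrices are min-max scaled per plant (compensating inter-plant
variability), labelled day/night from the local ephemeris and
stressed/normal from the irrigation schedule with a 3-hour stress-onset
delay, and split 80/20 into learning and validation sets.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import EphemerisTable, IrrigationSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "ClassBalance",
    "PlantMinMaxScaler",
    "normalize_features",
    "label_day_night",
    "label_drought",
    "class_balance",
    "split_dataset",
    "drop_incomplete_rows",
    "build_labelled_dataset",
]

LABEL_COLUMNS = ("label_daynight", "label_water")
ID_COLUMNS = ("plant_id", "timestamp")


def feature_columns(df: pd.DataFrame) -> list[str]:
    """The feature columns of a matrix: everything except ids and labels."""
    reserved = set(ID_COLUMNS) | set(LABEL_COLUMNS)
    return [c for c in df.columns if c not in reserved]


@dataclass(frozen=True)
class ClassBalance:
    counts: dict
    percentages: dict
    n: int


class PlantMinMaxScaler(TransformerMixin, BaseEstimator):
    """Min-max scale each feature column to [0, 1] per plant (or globally).

    The per-plant scope compensates for inter-plant baseline variability: with
    ``scope='per_plant'`` each plant's values of every non-constant feature
    attain 0 and 1.  Constant columns map to all zeros.

    Parameters
    ----------
    scope : {'per_plant', 'global'}
    """

    def __init__(self, scope: str = "per_plant"):
        self.scope = scope

    def fit(self, X: pd.DataFrame, y=None) -> "PlantMinMaxScaler":
        if self.scope not in ("per_plant", "global"):
            raise ValueError(f"unknown scope {self.scope!r}")
        cols = feature_columns(X)
        if not cols or len(X) == 0:
            raise ValueError("empty feature matrix")
        if X[cols].isna().any().any():
            raise ValueError("feature matrix contains missing values; drop them first")
        self.feature_columns_ = cols
        if self.scope == "per_plant":
            if "plant_id" not in X.columns:
                raise ValueError("per-plant scaling requires a plant_id column")
            grouped = X.groupby("plant_id", sort=True)[cols]
            self.min_ = grouped.min()
            self.max_ = grouped.max()
        else:
            self.min_ = X[cols].min().to_frame().T
            self.max_ = X[cols].max().to_frame().T
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = self.feature_columns_
        out = X.copy()
        if self.scope == "per_plant":
            for plant, idx in X.groupby("plant_id", sort=False).groups.items():
                if plant not in self.min_.index:
                    raise ValueError(f"plant {plant!r} was not seen during fit")
                lo = self.min_.loc[plant].to_numpy()
                hi = self.max_.loc[plant].to_numpy()
                span = hi - lo
                vals = X.loc[idx, cols].to_numpy()
                scaled = np.where(span > 0, (vals - lo) / np.where(span > 0, span, 1.0), 0.0)
                out.loc[idx, cols] = scaled
        else:
            lo = self.min_.iloc[0].to_numpy()
            hi = self.max_.iloc[0].to_numpy()
            span = hi - lo
            vals = X[cols].to_numpy()
            out[cols] = np.where(span > 0, (vals - lo) / np.where(span > 0, span, 1.0), 0.0)
        return out


def normalize_features(matrix: pd.DataFrame, scope: str = "per_plant") -> pd.DataFrame:
    """x_nf = (x_f - x_f,min) / (x_f,max - x_f,min) within the given scope."""
    return PlantMinMaxScaler(scope=scope).fit(matrix).transform(matrix)


def drop_incomplete_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop rows containing the NaN missing-value sentinel (logged count)."""
    cols = feature_columns(matrix)
    keep = ~matrix[cols].isna().any(axis=1)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d rows with missing features", n_drop)
    return matrix.loc[keep].reset_index(drop=True)


def label_day_night(timestamps, ephemeris: EphemerisTable) -> np.ndarray:
    """'day' iff sunrise <= clock time < sunset on the sample's date."""
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps))
    hours = (ts.hour + ts.minute / 60.0 + ts.second / 3600.0
             + ts.microsecond / 3.6e9).to_numpy()
    labels = np.empty(len(ts), dtype=object)
    for date in np.unique(ts.date):
        rise, set_ = ephemeris.sunrise_sunset(date)
        sel = np.asarray(ts.date) == date
        labels[sel] = np.where((hours[sel] >= rise) & (hours[sel] < set_),
                               "day", "night")
    return labels


def label_drought(timestamps, schedule: IrrigationSchedule,
                  delay_hours: float = 3.0) -> np.ndarray:
    """'stressed' iff irrigation has been below optimal for >= delay hours.

    The onset delay models the lag between reduced irrigation and the plant's
    physiological stress response; restoring full irrigation resets the state
    to 'normal' immediately.
    """
    t = schedule.seconds_from(pd.to_datetime(timestamps))
    run_start = schedule.deficit_run_start()
    seg = schedule.segment_index(t)
    level = schedule.levels[seg]
    onset = run_start[seg] + delay_hours * 3600.0
    stressed = (level < 1.0) & (t >= onset)
    return np.where(stressed, "stressed", "normal")


def class_balance(labels) -> ClassBalance:
    """Class counts and percentages (one decimal) of a label vector."""
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("cannot balance an empty label vector")
    values, counts = np.unique(arr, return_counts=True)
    n = int(arr.size)
    return ClassBalance(
        counts={str(v): int(c) for v, c in zip(values, counts)},
        percentages={str(v): round(100.0 * c / n, 1) for v, c in zip(values, counts)},
        n=n,
    )


def split_dataset(dataset: pd.DataFrame, train_fraction: float = 0.8,
                  seed: int = 0, method: str = "random",
                  stratify_on: str | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random row split into learning and validation sets.

    ``method='random'`` draws rows uniformly without replacement (the study
    protocol); ``method='by_day'`` assigns whole plant-days to one side, which
    avoids placing temporally adjacent samples on both sides.  The split is
    disjoint and exhaustive with ceil(f*n) training rows.
    """
    n = len(dataset)
    if n < 5:
        raise ValueError("dataset too small to split")
    rng = np.random.default_rng(seed)
    if method == "random":
        if stratify_on is not None:
            order = np.empty(0, dtype=np.int64)
            parts = []
            for _, idx in dataset.groupby(stratify_on, sort=True).groups.items():
                parts.append(rng.permutation(np.asarray(idx)))
            # interleave proportionally by taking the head of each class
            n_train = int(np.ceil(train_fraction * n))
            train_idx: list = []
            for part in parts:
                k = int(round(train_fraction * part.size))
                train_idx.extend(part[:k])
            train_idx = np.asarray(train_idx[:n_train])
            mask = np.zeros(n, dtype=bool)
            pos = dataset.index.get_indexer(train_idx)
            mask[pos] = True
        else:
            perm = rng.permutation(n)
            n_train = int(np.ceil(train_fraction * n))
            mask = np.zeros(n, dtype=bool)
            mask[perm[:n_train]] = True
    elif method == "by_day":
        days = pd.MultiIndex.from_arrays(
            [dataset["plant_id"], pd.to_datetime(dataset["timestamp"]).dt.date])
        uniq = days.unique()
        perm = rng.permutation(len(uniq))
        n_train_days = int(np.ceil(train_fraction * len(uniq)))
        train_days = set(uniq[perm[:n_train_days]])
        mask = np.asarray([d in train_days for d in days])
    else:
        raise ValueError(f"unknown split method {method!r}")
    train = dataset.loc[mask].reset_index(drop=True)
    test = dataset.loc[~mask].reset_index(drop=True)
    return train, test


def build_labelled_dataset(matrix: pd.DataFrame, schedule: IrrigationSchedule,
                           ephemeris: EphemerisTable, scope: str = "per_plant",
                           delay_hours: float = 3.0) -> pd.DataFrame:
    """Drop incomplete rows, normalize, and attach both label columns."""
    clean = drop_incomplete_rows(matrix)
    if len(clean) == 0:
        raise ValueError("no complete feature rows to label")
    norm = normalize_features(clean, scope=scope)
    norm["label_daynight"] = label_day_night(norm["timestamp"], ephemeris)
    norm["label_water"] = label_drought(norm["timestamp"], schedule,
                                        delay_hours=delay_hours)
    return norm
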