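"""Supervised classification of plant status from EP features.

Five model families mirror common practice for tabular biosignal features:
logistic regression (LR), a feedforward multilayer perceptron standing in for
"deep learning" (DL), a decision tree (DT), a random forest (RF) and gradient
boosted trees (GBT, via XGBoost).  Models are trained on the 182 normalized
feature columns only — never on identifiers or timestamps — and evaluated on
a held-out validation set with accuracy/precision/recall reported as
percentages for a stated positive class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from . import dataset as _ds
from .dataset import LABEL_COLUMNS, feature_columns

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "MetricsEntry",
    "train_models",
    "evaluate",
    "feature_importance",
    "run_pipeline",
    "PipelineConfig",
]

MODEL_FAMILIES = ("LR", "DL", "DT", "RF", "GBT")

TARGET_COLUMN = {"daynight": "label_daynight", "water": "label_water"}
#: default positive class per target (the majority class in the study design)
POSITIVE_CLASS = {"daynight": "day", "water": "normal"}


@dataclass(frozen=True)
class ModelSpec:
    """One classifier family plus hyperparameters and a seed.

    Defaults: GBT uses 200 trees of depth 6 at learning rate 0.1; DL is a
    2 x 50-unit rectified MLP with early stopping; RF grows 200 trees.
    ``params`` override the family defaults.
    """

    family: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}; "
                             f"expected one of {MODEL_FAMILIES}")

    def build(self):
        p = dict(self.params)
        if self.family == "LR":
            return LogisticRegression(max_iter=p.pop("max_iter", 2000), **p)
        if self.family == "DL":
            return MLPClassifier(
                hidden_layer_sizes=p.pop("hidden_layer_sizes", (50, 50)),
                activation=p.pop("activation", "relu"),
                early_stopping=p.pop("early_stopping", True),
                max_iter=p.pop("max_iter", 300),
                random_state=self.seed, **p)
        if self.family == "DT":
            return DecisionTreeClassifier(random_state=self.seed, **p)
        if self.family == "RF":
            return RandomForestClassifier(
                n_estimators=p.pop("n_estimators", 200),
                random_state=self.seed, n_jobs=p.pop("n_jobs", 1), **p)
        return XGBClassifier(
            n_estimators=p.pop("n_estimators", 200),
            max_depth=p.pop("max_depth", 6),
            learning_rate=p.pop("learning_rate", 0.1),
            tree_method=p.pop("tree_method", "hist"),
            random_state=self.seed, n_jobs=p.pop("n_jobs", 1), **p)


@dataclass(frozen=True)
class MetricsEntry:
    """Validation metrics of one model on one target (percentages, 1 decimal)."""

    model: str
    target: str
    positive_class: str
    accuracy: float
    precision: float
    recall: float
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_dict(self) -> dict:
        return {
            "model": self.model, "target": self.target,
            "positive_class": self.positive_class,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall,
            "confusion": {"tp": self.tp, "fp": self.fp,
                          "fn": self.fn, "tn": self.tn},
        }


def _check_no_leakage(cols: list[str]) -> None:
    banned = {"plant_id", "timestamp", *LABEL_COLUMNS}
    leaked = banned & set(cols)
    if leaked:
        raise ValueError(f"label/id columns leaked into the features: {sorted(leaked)}")


def train_models(train: pd.DataFrame, target: str,
                 specs: list[ModelSpec]) -> dict:
    """Fit one model per spec on the feature columns of the training set."""
    label_col = TARGET_COLUMN[target]
    cols = feature_columns(train)
    _check_no_leakage(cols)
    if len(train) == 0:
        raise ValueError("empty training set")
    y_raw = train[label_col].to_numpy()
    classes = np.unique(y_raw)
    if classes.size < 2:
        raise ValueError(f"training target {target!r} has a single class; unfittable")
    positive = POSITIVE_CLASS[target]
    y = (y_raw == positive).astype(int)  # positive class encoded as 1
    X = train[cols].to_numpy()
    fitted = {}
    for spec in specs:
        model = spec.build()
        model.fit(X, y)
        model.phytoep_feature_names_ = cols
        model.phytoep_positive_class_ = positive
        fitted[spec.family] = model
        logger.info("fitted %s on %d samples (%s)", spec.family, len(train), target)
    return fitted


def evaluate(model, test: pd.DataFrame, target: str,
             positive_class: str | None = None) -> MetricsEntry:
    """Accuracy, precision and recall of a fitted model on the validation set.

    Zero-denominator precision or recall is reported as 0 with a log notice.
    """
    if len(test) == 0:
        raise ValueError("empty validation set")
    label_col = TARGET_COLUMN[target]
    positive = positive_class or getattr(model, "phytoep_positive_class_",
                                         POSITIVE_CLASS[target])
    cols = getattr(model, "phytoep_feature_names_", feature_columns(test))
    y_true = (test[label_col].to_numpy() == positive).astype(int)
    y_pred = np.asarray(model.predict(test[cols].to_numpy())).astype(int)
    tp = int(((y_pred == 1) & (y_true == 1)).sum())
    fp = int(((y_pred == 1) & (y_true == 0)).sum())
    fn = int(((y_pred == 0) & (y_true == 1)).sum())
    tn = int(((y_pred == 0) & (y_true == 0)).sum())
    total = tp + fp + fn + tn
    accuracy = 100.0 * (tp + tn) / total
    if tp + fp == 0:
        logger.info("no positive predictions; precision defined as 0")
        precision = 0.0
    else:
        precision = 100.0 * tp / (tp + fp)
    if tp + fn == 0:
        logger.info("no positive truths; recall defined as 0")
        recall = 0.0
    else:
        recall = 100.0 * tp / (tp + fn)
    name = type(model).__name__
    return MetricsEntry(model=name, target=target, positive_class=positive,
                        accuracy=round(accuracy, 1), precision=round(precision, 1),
                        recall=round(recall, 1), tp=tp, fp=fp, fn=fn, tn=tn)


def feature_importance(model, feature_names: list[str] | None = None,
                       top_k: int | None = None) -> list[tuple[str, float]]:
    """Split-gain importances, normalized to sum to 1, sorted descending.

    Ties are broken by feature name so the ranking is deterministic.
    """
    names = feature_names or getattr(model, "phytoep_feature_names_", None)
    scores = getattr(model, "feature_importances_", None)
    if scores is None:
        raise ValueError("model does not expose feature_importances_")
    scores = np.asarray(scores, dtype=float)
    if names is None or len(names) != scores.size:
        raise ValueError("feature names do not match the importance vector")
    if (scores < 0).any():
        raise ValueError("importances must be non-negative")
    total = scores.sum()
    if total > 0:
        scores = scores / total
    ranked = sorted(zip(names, scores), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:top_k] if top_k else ranked


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full simulate-to-report run."""

    sim: "SimulationConfig"
    schedule_spans: tuple = ()          # (start_s, end_s, level); empty = full irrigation
    targets: tuple = ("daynight", "water")
    models: tuple = MODEL_FAMILIES
    train_fraction: float = 0.8
    split_method: str = "random"
    seed: int = 0


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """simulate -> filter -> features -> label -> split -> train -> evaluate.

    Returns a nested report dict (per target, per model: metrics plus top
    feature importances for tree models) and, when ``outdir`` is given,
    writes ``dataset.csv``, ``report.csv`` and ``report.json``.  Identical
    config produces an identical report.
    """
    from .synth import IrrigationSchedule, simulate_traces
    from .preprocess import apply_filters
    from .features import extract_features

    sim = config.sim
    if config.schedule_spans:
        schedule = IrrigationSchedule.from_spans(
            [tuple(s) for s in config.schedule_spans], origin=sim.start_time)
    else:
        schedule = IrrigationSchedule.constant(1.0, sim.duration_seconds,
                                               sim.start_time)
    from .synth import EphemerisTable
    n_days = int(np.ceil(sim.duration_days)) + 1
    ephemeris = EphemerisTable.constant(sim.start_time.date(), n_days,
                                        sim.sunrise_hour, sim.sunset_hour)

    traces = simulate_traces(sim, schedule, ephemeris)
    traces = [apply_filters(t) for t in traces]
    matrix = extract_features(traces)
    labelled = _ds.build_labelled_dataset(matrix, schedule, ephemeris)
    train, test = _ds.split_dataset(labelled, config.train_fraction,
                                    seed=config.seed, method=config.split_method)

    report: dict = {"seed": config.seed, "n_train": len(train),
                    "n_test": len(test), "targets": {}}
    rows = []
    for target in config.targets:
        specs = [ModelSpec(family, seed=config.seed) for family in config.models]
        fitted = train_models(train, target, specs)
        entries = {}
        for family in config.models:
            entry = evaluate(fitted[family], test, target)
            record = entry.as_dict()
            record["model"] = family
            if hasattr(fitted[family], "feature_importances_"):
                record["top_features"] = [
                    {"feature": f, "importance": round(float(v), 6)}
                    for f, v in feature_importance(fitted[family], top_k=10)]
            entries[family] = record
            rows.append({"target": target, "model": family,
                         "accuracy": entry.accuracy, "precision": entry.precision,
                         "recall": entry.recall})
        report["targets"][target] = entries

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        labelled.to_csv(outdir / "dataset.csv", index=False)
        pd.DataFrame(rows).to_csv(outdir / "report.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n")
        logger.info("pipeline artifacts written to %s", outdir)
    return report
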