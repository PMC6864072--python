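"""PCA exploration of raw daily-cycle signals.

Builds the two factorial-analysis matrices from decimated day cycles — X with
minutes as observations (1440 rows, one column per recorded day) for the
day/night question, and Z = X' with days as observations for the water-stress
question — runs a centred (optionally standardised) PCA, correlates component
scores with the raw variables, and computes p = 0.05 group covariance
ellipses for the factorial maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats
from sklearn.base import BaseEstimator

from .preprocess import MINUTES_PER_DAY, DayCycle
from .synth import IrrigationSchedule

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisMatrix",
    "PcaResult",
    "GroupEllipse",
    "build_matrices",
    "minute_day_night_classes",
    "day_water_classes",
    "FactorialPCA",
    "pca",
    "pc_raw_correlations",
    "confidence_ellipse",
]


@dataclass(frozen=True)
class AnalysisMatrix:
    """A cycles-by-minutes value block with row/column annotations.

    ``orientation`` is ``'minutes'`` (rows are minutes of day, columns are
    recorded days) or ``'days'`` (the transpose).
    """

    values: np.ndarray
    orientation: str
    row_ids: np.ndarray
    col_ids: np.ndarray
    row_classes: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValueError("analysis matrix contains non-finite cells")
        if v.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError("annotation lengths do not match the matrix shape")
        if self.row_classes is not None and len(self.row_classes) != v.shape[0]:
            raise ValueError("row_classes length does not match the matrix")


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray                    # observations x components
    loadings: np.ndarray                  # components x variables (kept)
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    kept_columns: np.ndarray              # indices into the input variables


@dataclass(frozen=True)
class GroupEllipse:
    group: str
    center: np.ndarray
    semi_axes: np.ndarray   # descending
    angle_rad: float
    n: int


def minute_day_night_classes(sunrise_hour: float = 6.0,
                             sunset_hour: float = 20.0) -> np.ndarray:
    minutes = np.arange(MINUTES_PER_DAY) / 60.0
    return np.where((minutes >= sunrise_hour) & (minutes < sunset_hour),
                    "day", "night")


def day_water_classes(cycles: list[DayCycle], schedule: IrrigationSchedule,
                      min_stress_hours: float = 6.0,
                      delay_hours: float = 3.0) -> np.ndarray:
    """Label each day cycle 'stress' or 'comfort' from the irrigation schedule.

    A day counts as stress when at least ``min_stress_hours`` of it fall after
    the stress onset (deficit sustained for the onset delay).
    """
    from .dataset import label_drought  # deferred: avoids an import cycle
    classes = []
    for c in cycles:
        ts = (np.datetime64(c.date, "s").astype("datetime64[us]")
              + (np.arange(MINUTES_PER_DAY) * 60e6).astype("timedelta64[us]"))
        lab = label_drought(ts, schedule, delay_hours=delay_hours)
        stressed_h = float((lab == "stressed").sum()) / 60.0
        classes.append("stress" if stressed_h >= min_stress_hours else "comfort")
    return np.asarray(classes)


def build_matrices(cycles: list[DayCycle],
                   minute_classes: np.ndarray | None = None,
                   day_classes: np.ndarray | None = None
                   ) -> tuple[AnalysisMatrix, AnalysisMatrix]:
    """(X minutes-as-rows, Z days-as-rows) from complete day cycles."""
    if not cycles:
        raise ValueError("no cycles supplied")
    values = np.column_stack([c.values for c in cycles])  # 1440 x n_days
    day_ids = np.asarray([f"{c.plant_id}/{c.date.isoformat()}" for c in cycles])
    minute_ids = np.arange(MINUTES_PER_DAY)
    X = AnalysisMatrix(values, "minutes", minute_ids, day_ids, minute_classes)
    Z = AnalysisMatrix(values.T, "days", day_ids, minute_ids, day_classes)
    return X, Z


class FactorialPCA(BaseEstimator):
    """PCA with column centring, optional unit scaling, and a fixed sign rule.

    Components are ordered by decreasing variance; each component's sign is
    chosen so that its largest-magnitude loading is positive, making the
    factorial maps deterministic.  Constant columns are dropped with a logged
    notice (they carry no variance and break unit scaling).

    Attributes (after ``fit``): ``scores_``, ``loadings_``,
    ``explained_variance_ratio_``, ``center_``, ``scale_``, ``kept_columns_``.
    """

    def __init__(self, n_components: int | None = None, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X, y=None) -> "FactorialPCA":
        V = np.asarray(X, dtype=float)
        if V.ndim != 2 or V.shape[0] < 2:
            raise ValueError("PCA needs a 2-d matrix with at least 2 observations")
        variable_sd = V.std(axis=0, ddof=1)
        keep = variable_sd > 0
        if not keep.all():
            logger.info("dropping %d constant column(s) before PCA",
                        int((~keep).sum()))
        if not keep.any():
            raise ValueError("all columns are constant")
        V = V[:, keep]
        center = V.mean(axis=0)
        scale = V.std(axis=0, ddof=1) if self.scale else np.ones(V.shape[1])
        W = (V - center) / scale
        U, s, Vt = np.linalg.svd(W, full_matrices=False)
        var = s ** 2
        ratio = var / var.sum() if var.sum() > 0 else var
        k = self.n_components or s.size
        k = min(k, s.size)
        scores = U[:, :k] * s[:k]
        loadings = Vt[:k]
        # deterministic sign: largest-magnitude loading positive per component
        for j in range(k):
            i = int(np.argmax(np.abs(loadings[j])))
            if loadings[j, i] < 0:
                loadings[j] *= -1.0
                scores[:, j] *= -1.0
        self.center_ = center
        self.scale_ = scale
        self.kept_columns_ = np.nonzero(keep)[0]
        self.loadings_ = loadings
        self.scores_ = scores
        self.explained_variance_ratio_ = ratio[:k]
        return self

    def transform(self, X) -> np.ndarray:
        V = np.asarray(X, dtype=float)[:, self.kept_columns_]
        return ((V - self.center_) / self.scale_) @ self.loadings_.T

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).scores_


def pca(matrix: AnalysisMatrix, scale: bool = True,
        n_components: int | None = None) -> PcaResult:
    """Run :class:`FactorialPCA` on an analysis matrix."""
    model = FactorialPCA(n_components=n_components, scale=scale).fit(matrix.values)
    return PcaResult(scores=model.scores_, loadings=model.loadings_,
                     explained_variance_ratio=model.explained_variance_ratio_,
                     center=model.center_, scale=model.scale_,
                     kept_columns=model.kept_columns_)


def pc_raw_correlations(result: PcaResult, matrix: AnalysisMatrix,
                        component: int = 0) -> np.ndarray:
    """Pearson correlation of one component's scores with each raw variable.

    Variables with zero variance (including the dropped constant columns)
    get correlation 0.
    """
    if not 0 <= component < result.scores.shape[1]:
        raise IndexError("component out of range")
    s = result.scores[:, component]
    sc = s - s.mean()
    V = matrix.values
    Vc = V - V.mean(axis=0)
    denom = np.sqrt((sc @ sc) * (Vc ** 2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, (Vc.T @ sc) / np.where(denom > 0, denom, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def confidence_ellipse(scores: np.ndarray, groups, p: float = 0.05) -> list[GroupEllipse]:
    """Per-group covariance ellipse of a 2-column score block.

    The ellipse is the chi-squared(2, 1-p) contour of the group mean and
    covariance: semi-axes sqrt(lambda_i * chi2_quantile) along the covariance
    eigenvectors.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != 2:
        raise ValueError("expected a 2-column score block")
    groups = np.asarray(groups)
    quantile = _stats.chi2.ppf(1.0 - p, df=2)
    out = []
    for g in np.unique(groups):
        pts = S[groups == g]
        if pts.shape[0] < 3:
            raise ValueError(f"group {g!r} has fewer than 3 members")
        center = pts.mean(axis=0)
        cov = np.cov(pts, rowvar=False)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1]
        eigvals = np.clip(eigvals[order], 0.0, None)
        lead = eigvecs[:, order[0]]
        out.append(GroupEllipse(group=str(g), center=center,
                                semi_axes=np.sqrt(eigvals * quantile),
                                angle_rad=float(np.arctan2(lead[1], lead[0])),
                                n=pts.shape[0]))
    return out
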