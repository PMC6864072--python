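"""Multi-scale window feature extraction for EP traces.

Every 5 minutes (the sampling step), seven trailing windows of 15 s to 30 min
that share their right edge at the sample time are cut from the native-rate
signal, and 26 features are computed in each window:

* 7 simple statistics — min, max, mean, population variance, Fisher skewness,
  excess kurtosis, interquartile range;
* 2 Hjorth parameters — mobility and complexity;
* 1 generalized Hurst exponent at moment order q = 2;
* 2 wavelet entropies — Shannon and log-energy (Haar decomposition);
* 5 noise-colour indicators — a one-hot over white/pink/brown/blue/purple from
  the fitted log-log periodogram slope;
* 9 wavelet-decomposition statistics — min/max/mean of the single-level detail
  coefficients for Daubechies orders 1, 4 and 8.

With the default seven window sizes this yields 182 features per sample.  The
heavy lifting is vectorised: all windows of one size form the rows of a 2-D
array and each feature family is computed along the last axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as _sig
from sklearn.base import BaseEstimator, TransformerMixin

from .synth import SignalTrace

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "WINDOW_FEATURE_NAMES",
    "NOISE_COLOURS",
    "extract_windows",
    "statistical_features",
    "hjorth_parameters",
    "generalized_hurst",
    "wavelet_entropy",
    "wavelet_entropy_from_energies",
    "noise_color",
    "classify_spectral_slope",
    "wavelet_decomp_stats",
    "feature_vector",
    "MultiScaleFeatureExtractor",
    "extract_features",
]

#: per-window feature names, in output order
WINDOW_FEATURE_NAMES: tuple[str, ...] = (
    "min", "max", "mean", "variance", "skewness", "kurtosis", "iqr",
    "hjorth_mobility", "hjorth_complexity",
    "hurst_q2",
    "went_shannon", "went_log",
    "noise_white", "noise_pink", "noise_brown", "noise_blue", "noise_purple",
    "wd1_min", "wd1_max", "wd1_mean",
    "wd4_min", "wd4_max", "wd4_mean",
    "wd8_min", "wd8_max", "wd8_mean",
)

#: noise colour -> target slope of log10 PSD vs log10 f (PSD ~ f**slope)
NOISE_COLOURS: tuple[tuple[str, float], ...] = (
    ("white", 0.0), ("pink", -1.0), ("brown", -2.0), ("blue", 1.0), ("purple", 2.0),
)

LOG_ENERGY_FLOOR = 1e-12

# Minimum window lengths per feature family.  The Hurst and noise-colour
# minima are set by what their estimators need (>=2 lag points for the scaling
# fit; >=15 non-DC periodogram bins for the slope fit) so that the shortest
# 15 s window remains computable at the 4 Hz desk-scale rate.
MIN_STATS = 2
MIN_HJORTH = 3
MIN_HURST = 20
MIN_ENTROPY = 4
MIN_NOISE = 32
MIN_WAVELET = 16  # db8 filter support

HURST_MAX_LAG = 19


@dataclass(frozen=True)
class WindowSpec:
    """Sampling step and the trailing window sizes, both in seconds."""

    step: float = 300.0
    sizes: tuple = (15.0, 30.0, 60.0, 120.0, 300.0, 600.0, 1800.0)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if len(self.sizes) == 0 or any(np.diff(self.sizes) <= 0):
            raise ValueError("window sizes must be strictly increasing")

    @property
    def max_size(self) -> float:
        return self.sizes[-1]

    def feature_names(self) -> list[str]:
        return [f"w{int(round(w))}s_{name}"
                for w in self.sizes for name in WINDOW_FEATURE_NAMES]


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------


def sample_offsets(duration_s: float, spec: WindowSpec) -> np.ndarray:
    """Sample times t = max_size, max_size+step, ... <= duration (seconds)."""
    if duration_s < spec.max_size:
        return np.empty(0)
    n = int(np.floor((duration_s - spec.max_size) / spec.step)) + 1
    return spec.max_size + spec.step * np.arange(n)


def extract_windows(trace: SignalTrace,
                    spec: WindowSpec = WindowSpec()) -> list[tuple[float, list[np.ndarray]]]:
    """Cut the trailing windows [t - w, t) for every sample time t.

    Returns (time-offset seconds, [window arrays in increasing-size order])
    per sample; an empty list (logged) when the trace is shorter than the
    largest window.
    """
    offsets = sample_offsets(trace.duration_seconds, spec)
    if offsets.size == 0:
        logger.info("trace %s shorter than the largest window; no samples",
                    trace.plant_id)
        return []
    rate = trace.sample_rate
    out = []
    for t in offsets:
        end = int(round(t * rate))
        windows = [trace.values[end - int(round(w * rate)):end] for w in spec.sizes]
        out.append((float(t), windows))
    return out


# ---------------------------------------------------------------------------
# Feature families (vectorised along the last axis of a 2-D window block)
# ---------------------------------------------------------------------------


def _stats_block(W: np.ndarray) -> np.ndarray:
    mean = W.mean(axis=1)
    xc = W - mean[:, None]
    m2 = (xc ** 2).mean(axis=1)
    m3 = (xc ** 3).mean(axis=1)
    m4 = (xc ** 4).mean(axis=1)
    ok = m2 > 0
    skew = np.zeros_like(m2)
    kurt = np.zeros_like(m2)
    skew[ok] = m3[ok] / m2[ok] ** 1.5
    kurt[ok] = m4[ok] / m2[ok] ** 2 - 3.0
    q1, q3 = np.percentile(W, [25, 75], axis=1)
    return np.column_stack([W.min(axis=1), W.max(axis=1), mean, m2,
                            skew, kurt, q3 - q1])


def _hjorth_block(W: np.ndarray) -> np.ndarray:
    d1 = np.diff(W, axis=1)
    d2 = np.diff(d1, axis=1)
    v0 = W.var(axis=1)
    v1 = d1.var(axis=1)
    v2 = d2.var(axis=1)
    mobility = np.where(v0 > 0, np.sqrt(np.divide(v1, v0, where=v0 > 0,
                                                  out=np.zeros_like(v0))), 0.0)
    mob_d = np.where(v1 > 0, np.sqrt(np.divide(v2, v1, where=v1 > 0,
                                               out=np.zeros_like(v1))), 0.0)
    complexity = np.where(mobility > 0,
                          np.divide(mob_d, mobility, where=mobility > 0,
                                    out=np.zeros_like(mobility)), 0.0)
    return np.column_stack([mobility, complexity])


def _hurst_block(W: np.ndarray, q: float = 2.0) -> np.ndarray:
    """Generalized Hurst exponent per row via the scaling of the q-th
    structure function K_q(tau) = <|x(t+tau) - x(t)|^q> over tau = 1..tau_max;
    H is the log-log slope divided by q, clipped to [-0.5, 1.5]."""
    m, n = W.shape
    tau_max = min(HURST_MAX_LAG, n // 10)
    taus = np.arange(1, tau_max + 1)
    K = np.empty((m, tau_max))
    for i, tau in enumerate(taus):
        K[:, i] = np.mean(np.abs(W[:, tau:] - W[:, :-tau]) ** q, axis=1)
    degenerate = (K <= 0).any(axis=1)
    lt = np.log(taus)
    lK = np.log(np.where(K > 0, K, 1.0))
    ltc = lt - lt.mean()
    slope = (lK @ ltc) / (ltc @ ltc)
    H = np.clip(slope / q, -0.5, 1.5)
    H[degenerate] = 0.0
    return H[:, None]


def _entropy_block(W: np.ndarray) -> np.ndarray:
    """Shannon and log-energy wavelet entropies from a multilevel Haar
    decomposition (L = min(floor(log2 n), 8) levels)."""
    n = W.shape[1]
    level = min(int(np.floor(np.log2(n))), 8)
    coeffs = pywt.wavedec(W, "haar", level=level, axis=-1)
    energies = np.stack([(c ** 2).sum(axis=-1) for c in coeffs])  # (L+1, m)
    total = energies.sum(axis=0)
    ok = total > 0
    p = np.zeros_like(energies)
    p[:, ok] = energies[:, ok] / total[ok]
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    shannon = -plogp.sum(axis=0)
    log_energy = sum(np.log(np.maximum(c ** 2, LOG_ENERGY_FLOOR)).sum(axis=-1)
                     for c in coeffs)
    return np.column_stack([shannon, log_energy])


def wavelet_entropy_from_energies(energies: np.ndarray) -> float:
    """Shannon entropy of a subband-energy distribution (0*ln 0 = 0)."""
    e = np.asarray(energies, dtype=float)
    total = e.sum()
    if total <= 0:
        return 0.0
    p = e / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def classify_spectral_slope(slope: float) -> str:
    """Nearest noise-colour target slope; ties go to the smaller |target|."""
    best = min(NOISE_COLOURS, key=lambda c: (abs(slope - c[1]), abs(c[1]), c[1]))
    return best[0]


def _noise_block(W: np.ndarray, rate: float) -> np.ndarray:
    freqs, psd = _sig.periodogram(W, fs=rate, window="hann",
                                  detrend="constant", axis=-1)
    freqs, psd = freqs[1:], psd[:, 1:]
    lf = np.log10(freqs)
    lfc = lf - lf.mean()
    denom = lfc @ lfc
    onehot = np.zeros((W.shape[0], len(NOISE_COLOURS)))
    positive = psd > 0
    all_pos = positive.all(axis=1)
    slopes = np.zeros(W.shape[0])
    if all_pos.any():
        lp = np.log10(psd[all_pos])
        slopes[all_pos] = (lp @ lfc) / denom
    for r in np.nonzero(~all_pos)[0]:
        mask = positive[r]
        if mask.sum() >= 2:
            x = lf[mask] - lf[mask].mean()
            slopes[r] = (np.log10(psd[r, mask]) @ x) / (x @ x)
        # else: degenerate (e.g. constant window) -> slope 0 -> white
    names = [c[0] for c in NOISE_COLOURS]
    for r, s in enumerate(slopes):
        onehot[r, names.index(classify_spectral_slope(float(s)))] = 1.0
    return onehot


def _wavedec_stats_block(W: np.ndarray) -> np.ndarray:
    cols = []
    for order in (1, 4, 8):
        _, detail = pywt.dwt(W, f"db{order}", axis=-1)
        cols += [detail.min(axis=-1), detail.max(axis=-1), detail.mean(axis=-1)]
    return np.column_stack(cols)


_FAMILIES = (
    # (column slice into WINDOW_FEATURE_NAMES, min length, function(W, rate))
    (slice(0, 7), MIN_STATS, lambda W, rate: _stats_block(W)),
    (slice(7, 9), MIN_HJORTH, lambda W, rate: _hjorth_block(W)),
    (slice(9, 10), MIN_HURST, lambda W, rate: _hurst_block(W)),
    (slice(10, 12), MIN_ENTROPY, lambda W, rate: _entropy_block(W)),
    (slice(12, 17), MIN_NOISE, lambda W, rate: _noise_block(W, rate)),
    (slice(17, 26), MIN_WAVELET, lambda W, rate: _wavedec_stats_block(W)),
)


def window_feature_block(W: np.ndarray, rate: float) -> np.ndarray:
    """All 26 features for each row of a 2-D window block.

    Families whose minimum length exceeds the window length are filled with
    the NaN missing-value sentinel (logged once per call).
    """
    W = np.atleast_2d(np.asarray(W, dtype=float))
    m, n = W.shape
    out = np.full((m, len(WINDOW_FEATURE_NAMES)), np.nan)
    for cols, min_len, fn in _FAMILIES:
        if n >= min_len:
            out[:, cols] = fn(W, rate)
        else:
            logger.warning("window length %d below minimum %d for features %s; "
                           "NaN sentinel used", n, min_len,
                           WINDOW_FEATURE_NAMES[cols])
    return out


# ---------------------------------------------------------------------------
# Single-window API
# ---------------------------------------------------------------------------


def statistical_features(window: Sequence[float]) -> np.ndarray:
    """min, max, mean, population variance, skewness, excess kurtosis, IQR."""
    w = np.asarray(window, dtype=float)
    if w.size < MIN_STATS:
        raise ValueError("statistical features need at least 2 samples")
    return _stats_block(w[None, :])[0]

def hjorth_parameters(window: Sequence[float]) -> tuple[float, float]:
    """Hjorth mobility sqrt(var(dx)/var(x)) and complexity mobility(dx)/mobility(x)."""
    w = np.asarray(window, dtype=float)
    if w.size < MIN_HJORTH:
        raise ValueError("Hjorth parameters need at least 3 samples")
    mob, comp = _hjorth_block(w[None, :])[0]
    return float(mob), float(comp)

def generalized_hurst(window: Sequence[float], q: float = 2.0) -> float:
    """Generalized Hurst exponent H(q); NaN sentinel below the minimum length."""
    w = np.asarray(window, dtype=float)
    if w.size < MIN_HURST:
        logger.warning("window of %d samples too short for the Hurst exponent; "
                       "NaN sentinel", w.size)
        return float("nan")
    return float(_hurst_block(w[None, :], q=q)[0, 0])

def wavelet_entropy(window: Sequence[float]) -> tuple[float, float]:
    """(Shannon, log-energy) wavelet entropies of the window."""
    w = np.asarray(window, dtype=float)
    if w.size < MIN_ENTROPY:
        raise ValueError("wavelet entropy needs at least 4 samples")
    sh, le = _entropy_block(w[None, :])[0]
    return float(sh), float(le)

def noise_color(window: Sequence[float], rate: float) -> np.ndarray:
    """One-hot noise-colour indicator (white, pink, brown, blue, purple)."""
    w = np.asarray(window, dtype=float)
    if w.size < MIN_NOISE:
        raise ValueError("noise-colour estimation needs at least "
                         f"{MIN_NOISE} samples")
    return _noise_block(w[None, :], rate)[0]

def wavelet_decomp_stats(window: Sequence[float]) -> np.ndarray:
    """min/max/mean of single-level db1, db4, db8 detail coefficients."""
    w = np.asarray(window, dtype=float)
    if w.size < MIN_WAVELET:
        raise ValueError("wavelet decomposition stats need at least "
                         f"{MIN_WAVELET} samples")
    return _wavedec_stats_block(w[None, :])[0]


def feature_vector(timestamp: float, windows: Sequence[np.ndarray],
                   spec: WindowSpec = WindowSpec(),
                   rate: float = 4.0) -> np.ndarray:
    """Concatenate the per-window feature blocks of one sample (7 x 26 = 182)."""
    if len(windows) != len(spec.sizes):
        raise ValueError(f"expected {len(spec.sizes)} windows, got {len(windows)}")
    blocks = [window_feature_block(np.asarray(w, dtype=float)[None, :], rate)[0]
              for w in windows]
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# Estimator
# ---------------------------------------------------------------------------


class MultiScaleFeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless transformer: EP traces -> multi-scale feature matrix.

    ``transform`` accepts a sequence of :class:`~phytoep.synth.SignalTrace`
    and returns a DataFrame with ``plant_id``, ``timestamp`` and one column
    per feature (window size x feature family).

    Parameters
    ----------
    step : float
        Sampling step between consecutive feature vectors, seconds.
    sizes : tuple of float
        Trailing window sizes, seconds, strictly increasing.
    """

    def __init__(self, step: float = 300.0,
                 sizes: tuple = (15.0, 30.0, 60.0, 120.0, 300.0, 600.0, 1800.0)):
        self.step = step
        self.sizes = sizes

    def _spec(self) -> WindowSpec:
        return WindowSpec(step=self.step, sizes=tuple(self.sizes))

    def fit(self, X=None, y=None) -> "MultiScaleFeatureExtractor":
        spec = self._spec()
        self.feature_names_ = spec.feature_names()
        self.n_features_out_ = len(self.feature_names_)
        return self

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.asarray(self._spec().feature_names(), dtype=object)

    def transform(self, X: Sequence[SignalTrace]) -> pd.DataFrame:
        spec = self._spec()
        names = spec.feature_names()
        frames = []
        for trace in X:
            offsets = sample_offsets(trace.duration_seconds, spec)
            if offsets.size == 0:
                logger.info("trace %s shorter than the largest window; skipped",
                            trace.plant_id)
                continue
            rate = trace.sample_rate
            end_idx = np.rint(offsets * rate).astype(np.int64)
            blocks = []
            for w in spec.sizes:
                wlen = int(round(w * rate))
                view = sliding_window_view(trace.values, wlen)
                blocks.append(window_feature_block(view[end_idx - wlen], rate))
            feats = np.hstack(blocks)
            start = np.datetime64(trace.start_time, "us")
            ts = start + (offsets * 1e6).astype("timedelta64[us]")
            df = pd.DataFrame(feats, columns=names)
            df.insert(0, "timestamp", ts)
            df.insert(0, "plant_id", trace.plant_id)
            frames.append(df)
        if not frames:
            return pd.DataFrame(columns=["plant_id", "timestamp"] + names)
        return pd.concat(frames, ignore_index=True)


def extract_features(traces: Sequence[SignalTrace],
                     spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Functional wrapper over :class:`MultiScaleFeatureExtractor`."""
    return MultiScaleFeatureExtractor(step=spec.step,
                                      sizes=spec.sizes).fit().transform(traces)
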