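"""Window feature families versus independent brute-force oracles.

Each family is checked against a from-scratch reimplementation of its
defining formula (loops / hardcoded filter constants / closed forms), on
random windows and on cases with known analytic values.
"""

import numpy as np
import pytest
from scipy import stats as sps

from phytoep.features import (MIN_HURST, MIN_NOISE, WINDOW_FEATURE_NAMES,
                              MultiScaleFeatureExtractor, WindowSpec,
                              classify_spectral_slope, extract_windows,
                              feature_vector, generalized_hurst,
                              hjorth_parameters, noise_color,
                              statistical_features, wavelet_decomp_stats,
                              wavelet_entropy, wavelet_entropy_from_energies,
                              window_feature_block)
from phytoep.synth import SignalTrace, colored_noise

import datetime as dt

START = dt.datetime(2018, 6, 1)


def make_trace(values, rate):
    return SignalTrace(plant_id="p0", start_time=START, sample_rate=rate,
                       values=np.asarray(values, dtype=float))


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_hjorth(x):
    var = lambda v: float(np.mean((v - np.mean(v)) ** 2))
    d1, d2 = np.diff(x), np.diff(np.diff(x))
    mob = np.sqrt(var(d1) / var(x))
    return mob, np.sqrt(var(d2) / var(d1)) / mob


def brute_hurst(x, q=2.0):
    tau_max = min(19, len(x) // 10)
    K = [np.mean(np.abs(x[tau:] - x[:-tau]) ** q) for tau in range(1, tau_max + 1)]
    slope = np.polyfit(np.log(np.arange(1, tau_max + 1)), np.log(K), 1)[0]
    return float(np.clip(slope / q, -0.5, 1.5))


def brute_haar_entropies(x):
    """Haar cascade by explicit pairwise averaging/differencing (power-of-2 n)."""
    n = len(x)
    levels = min(int(np.log2(n)), 8)
    a = np.asarray(x, dtype=float)
    subband_energies, all_sq = [], []
    for _ in range(levels):
        d = (a[0::2] - a[1::2]) / np.sqrt(2.0)
        a = (a[0::2] + a[1::2]) / np.sqrt(2.0)
        subband_energies.append(np.sum(d ** 2))
        all_sq.append(d ** 2)
    subband_energies.append(np.sum(a ** 2))
    all_sq.append(a ** 2)
    p = np.asarray(subband_energies) / np.sum(subband_energies)
    p = p[p > 0]
    shannon = float(-(p * np.log(p)).sum())
    log_energy = float(sum(np.log(np.maximum(sq, 1e-12)).sum() for sq in all_sq))
    return shannon, log_energy


def brute_noise_slope(x, rate):
    """Hann-windowed mean-removed one-sided periodogram, log-log least squares."""
    n = len(x)
    win = np.hanning(n + 1)[:-1]  # periodic Hann
    psd = np.abs(np.fft.rfft((x - x.mean()) * win)) ** 2
    psd[1:] *= 2.0              # one-sided convention ...
    if n % 2 == 0:
        psd[-1] /= 2.0          # ... except the Nyquist bin
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    return np.polyfit(np.log10(f[1:]), np.log10(psd[1:]), 1)[0]


# independently tabulated Daubechies decomposition low-pass filters
DB_DEC_LO = {
    1: np.array([0.7071067811865476, 0.7071067811865476]),
    4: np.array([-0.010597401784997278, 0.032883011666982945,
                 0.030841381835986965, -0.18703481171888114,
                 -0.02798376941698385, 0.6308807679295904,
                 0.7148465705525415, 0.23037781330885523]),
    8: np.array([-0.00011747678400228192, 0.0006754494059985568,
                 -0.0003917403729959771, -0.00487035299301066,
                 0.008746094047015655, 0.013981027917015516,
                 -0.04408825393106472, -0.01736930100202211,
                 0.128747426620186, 0.00047248457399797254,
                 -0.2840155429624281, -0.015829105256023893,
                 0.5853546836548691, 0.6756307362980128,
                 0.3128715909144659, 0.05441584224308161]),
}


def brute_dwt_detail(x, order):
    """Single-level DWT detail coefficients: symmetric edge extension by
    (filter length - 1), full convolution, downsample odd indices."""
    lo = DB_DEC_LO[order]
    flen = len(lo)
    # quadrature mirror: hi[k] = (-1)^(k+1) * lo[flen-1-k]
    hi = lo[::-1] * (-1.0) ** (np.arange(flen) + 1)
    ext = np.concatenate([x[:flen - 1][::-1], x, x[-(flen - 1):][::-1]])
    return np.convolve(ext, hi, mode="valid")[1::2]


# ---------------------------------------------------------------------------
# Statistical features
# ---------------------------------------------------------------------------


class TestStatisticalFeatures:
    def test_symmetric_small_case(self):
        f = statistical_features([1, 2, 3, 4])
        np.testing.assert_allclose(f[:5], [1, 4, 2.5, 1.25, 0.0])
        assert f[6] == pytest.approx(1.5)  # IQR, linear-interp quantiles

    def test_against_scipy_on_random_windows(self, rng):
        for _ in range(100):
            x = rng.standard_normal(rng.integers(5, 200))
            f = statistical_features(x)
            expected = [x.min(), x.max(), x.mean(), x.var(),
                        sps.skew(x), sps.kurtosis(x),
                        np.percentile(x, 75) - np.percentile(x, 25)]
            np.testing.assert_allclose(f, expected, atol=1e-8)

    def test_constant_window_degenerate_rule(self):
        f = statistical_features(np.full(50, 2.0))
        np.testing.assert_allclose(f, [2, 2, 2, 0, 0, 0, 0])

    def test_too_short(self):
        with pytest.raises(ValueError):
            statistical_features([1.0])


class TestHjorthParameters:
    def test_constant_window(self):
        assert hjorth_parameters(np.ones(50)) == (0.0, 0.0)

    def test_sinusoid_mobility_closed_form(self):
        # mobility of a sampled sinusoid of digital frequency f is 2 sin(pi f)
        f = 0.01
        x = np.sin(2 * np.pi * f * np.arange(10000))
        mob, _ = hjorth_parameters(x)
        assert mob == pytest.approx(2 * np.sin(np.pi * f), rel=1e-2)

    def test_iid_gaussian_complexity(self, rng):
        # var(dx) = 2 sigma^2 and var(d2x) = 6 sigma^2 -> complexity sqrt(3/2)
        _, comp = hjorth_parameters(rng.standard_normal(100_000))
        assert comp == pytest.approx(np.sqrt(1.5), abs=0.02)

    def test_against_brute_force(self, rng):
        for _ in range(100):
            x = rng.standard_normal(rng.integers(10, 300))
            np.testing.assert_allclose(hjorth_parameters(x), brute_hjorth(x),
                                       atol=1e-8)


class TestGeneralizedHurst:
    def test_linear_trend_is_one(self):
        assert generalized_hurst(np.arange(500.0)) == pytest.approx(1.0, abs=1e-9)

    def test_white_noise_near_zero(self):
        H = [generalized_hurst(colored_noise(4096, 0.0, 1.0, s)) for s in range(20)]
        assert abs(np.mean(H)) < 0.1

    def test_brownian_near_half(self):
        H = [generalized_hurst(np.cumsum(colored_noise(4096, 0.0, 1.0, s)))
             for s in range(20)]
        assert abs(np.mean(H) - 0.5) < 0.1

    def test_against_brute_force(self, rng):
        for _ in range(100):
            x = np.cumsum(rng.standard_normal(rng.integers(MIN_HURST, 500)))
            assert generalized_hurst(x) == pytest.approx(brute_hurst(x), abs=1e-8)

    def test_short_window_sentinel(self):
        assert np.isnan(generalized_hurst(np.arange(float(MIN_HURST - 1))))


class TestWaveletEntropy:
    def test_single_subband_zero_entropy(self):
        # constant signal: all detail energy vanishes -> one occupied subband
        sh, _ = wavelet_entropy(np.full(256, 3.0))
        assert sh == pytest.approx(0.0, abs=1e-12)

    def test_uniform_energies_give_log_j(self):
        for j in (2, 5, 9):
            assert wavelet_entropy_from_energies(np.ones(j)) == pytest.approx(np.log(j))

    def test_zero_energy_defined_as_zero(self):
        sh, _ = wavelet_entropy(np.zeros(64))
        assert sh == 0.0

    def test_against_brute_haar_cascade(self, rng):
        for _ in range(100):
            n = int(2 ** rng.integers(3, 11))
            x = rng.standard_normal(n)
            sh, le = wavelet_entropy(x)
            bsh, ble = brute_haar_entropies(x)
            assert sh == pytest.approx(bsh, abs=1e-8)
            assert le == pytest.approx(ble, rel=1e-8)

    def test_too_short(self):
        with pytest.raises(ValueError):
            wavelet_entropy([1.0, 2.0])


class TestNoiseColor:
    def test_white_noise_classified_white(self):
        hits = sum(noise_color(colored_noise(4096, 0.0, 1.0, s), 4.0)[0] == 1.0
                   for s in range(20))
        assert hits >= 18

    def test_brown_from_cumsum_of_white(self):
        onehot = noise_color(np.cumsum(colored_noise(4096, 0.0, 1.0, 0)), 4.0)
        assert onehot[2] == 1.0  # brown

    def test_one_hot_contract(self, rng):
        onehot = noise_color(rng.standard_normal(256), 4.0)
        assert onehot.sum() == 1.0 and set(onehot) <= {0.0, 1.0}

    def test_tie_rule(self):
        assert classify_spectral_slope(-0.5) == "white"   # tie 0 vs -1
        assert classify_spectral_slope(-1.5) == "pink"    # tie -1 vs -2
        assert classify_spectral_slope(1.5) == "blue"
        assert classify_spectral_slope(-2.7) == "brown"

    def test_slope_against_brute_periodogram(self, rng):
        for _ in range(50):
            x = np.cumsum(rng.standard_normal(int(rng.integers(MIN_NOISE, 600))))
            slope = brute_noise_slope(x, 4.0)
            expected = classify_spectral_slope(slope)
            names = ("white", "pink", "brown", "blue", "purple")
            got = names[int(np.argmax(noise_color(x, 4.0)))]
            assert got == expected

    def test_too_short(self):
        with pytest.raises(ValueError):
            noise_color(np.zeros(MIN_NOISE - 1), 4.0)


class TestWaveletDecompStats:
    def test_constant_gives_nine_zeros(self):
        np.testing.assert_allclose(wavelet_decomp_stats(np.full(64, 5.0)),
                                   np.zeros(9), atol=1e-10)

    def test_ramp_interior_details_vanish(self):
        # db4/db8 have >= 2 vanishing moments: a linear ramp leaves only
        # boundary detail coefficients
        x = np.linspace(0, 1, 128)
        for order in (4, 8):
            d = brute_dwt_detail(x, order)
            interior = d[len(DB_DEC_LO[order]) // 2: -len(DB_DEC_LO[order]) // 2]
            np.testing.assert_allclose(interior, 0.0, atol=1e-10)

    def test_order_statistics_contract(self, rng):
        v = wavelet_decomp_stats(rng.standard_normal(200))
        for k in range(0, 9, 3):
            assert v[k] <= v[k + 2] <= v[k + 1]  # min <= mean <= max

    def test_against_brute_force(self, rng):
        for _ in range(100):
            x = rng.standard_normal(int(rng.integers(16, 300)))
            got = wavelet_decomp_stats(x)
            expected = []
            for order in (1, 4, 8):
                d = brute_dwt_detail(x, order)
                expected += [d.min(), d.max(), d.mean()]
            np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_too_short(self):
        with pytest.raises(ValueError):
            wavelet_decomp_stats(np.zeros(15))


# ---------------------------------------------------------------------------
# Windowing and assembly
# ---------------------------------------------------------------------------


class TestExtractWindows:
    def test_one_hour_default_spec(self):
        trace = make_trace(np.zeros(4 * 3600), 4.0)
        samples = extract_windows(trace)
        assert len(samples) == 7
        np.testing.assert_allclose([t for t, _ in samples],
                                   1800 + 300 * np.arange(7))

    def test_window_lengths_and_shared_right_edge(self):
        rate = 4.0
        trace = make_trace(np.arange(4 * 3600.0), rate)
        t, windows = extract_windows(trace)[0]
        for w, size in zip(windows, WindowSpec().sizes):
            assert w.size == int(size * rate)
            assert w[-1] == int(t * rate) - 1  # right edge at the sample time

    def test_short_trace_empty(self):
        trace = make_trace(np.zeros(4 * 1200), 4.0)  # 20 min < 30 min window
        assert extract_windows(trace) == []


class TestFeatureVector:
    def test_length_182_and_unique_names(self):
        spec = WindowSpec()
        names = spec.feature_names()
        assert len(names) == 7 * 26 == 182
        assert len(set(names)) == 182
        assert len(WINDOW_FEATURE_NAMES) == 26
        assert names[7 * 26 - 26] == "w1800s_min"

    def test_identical_windows_identical_blocks(self, rng):
        spec = WindowSpec(sizes=(32.0, 64.0))
        w = rng.standard_normal(128)
        vec = feature_vector(0.0, [w, w], spec=spec, rate=2.0)
        np.testing.assert_array_equal(vec[:26], vec[26:])

    def test_wrong_window_count(self):
        with pytest.raises(ValueError):
            feature_vector(0.0, [np.zeros(64)])

    def test_invariants_on_window_block(self, rng):
        W = rng.standard_normal((40, 240))
        F = window_feature_block(W, rate=4.0)
        names = list(WINDOW_FEATURE_NAMES)
        assert np.isfinite(F).all()
        assert (F[:, names.index("variance")] >= 0).all()
        assert (F[:, names.index("min")] <= F[:, names.index("mean")]).all()
        assert (F[:, names.index("mean")] <= F[:, names.index("max")]).all()
        noise = F[:, names.index("noise_white"):names.index("noise_purple") + 1]
        np.testing.assert_allclose(noise.sum(axis=1), 1.0)


class TestExtractorDeterminismAndBlockPath:
    def test_transform_matches_single_window_path(self, rng):
        values = np.cumsum(rng.standard_normal(4 * 3600))
        trace = make_trace(values, 4.0)
        df = MultiScaleFeatureExtractor().fit().transform([trace])
        spec = WindowSpec()
        names = spec.feature_names()
        for i, (t, windows) in enumerate(extract_windows(trace, spec)):
            vec = feature_vector(t, windows, spec=spec, rate=4.0)
            np.testing.assert_allclose(df.loc[i, names].to_numpy(dtype=float),
                                       vec, atol=1e-10)

    def test_deterministic(self, rng):
        trace = make_trace(rng.standard_normal(4 * 3600), 4.0)
        a = MultiScaleFeatureExtractor().fit().transform([trace])
        b = MultiScaleFeatureExtractor().fit().transform([trace])
        assert a.equals(b)

    def test_sklearn_params_roundtrip(self):
        est = MultiScaleFeatureExtractor(step=60.0, sizes=(15.0, 30.0))
        params = est.get_params()
        clone = MultiScaleFeatureExtractor(**params)
        assert clone.get_params() == params
        assert list(clone.fit().get_feature_names_out()) == \
            ["w15s_" + n for n in WINDOW_FEATURE_NAMES] + \
            ["w30s_" + n for n in WINDOW_FEATURE_NAMES]
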