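# Methods

`phytoep` re-implements, as a tested pipeline on synthetic data, a workflow for
classifying plant physiological status (day/night phase and drought stress)
from extracellular electrical-potential (EP) recordings: signal simulation,
acquisition-chain emulation, multi-scale feature extraction, per-plant
normalization and labelling, PCA exploration, and supervised classification.
This note records the model, the parameters that matter, and the design
decisions taken where the design was genuinely open.

## The synthetic EP generator

No public EP recordings accompany this problem setting, so the package ships a
generator whose output reproduces the phenomenology the analysis relies on.
Per plant, the simulated trace is

    EP(t) = b_i + s(t) + a^{E(t)} * D(t) + eta(t)

* **Plant baseline** `b_i ~ N(baseline, baseline_sd_between_plants^2)`, drawn
  once per plant (defaults 20 mV, 5 mV). EP baselines differ substantially
  between individual plants, which is why the feature normalization below is
  per-plant.
* **Diel component** `D(t)`: an asymmetric raised-cosine bump, zero with zero
  slope outside daylight, rising from sunrise (06:00) to the peak value
  `diel_amplitude` (15 mV) at `diel_peak_hour` (14:00, the local solar noon of
  the emulated greenhouse), and falling to zero at sunset (20:00). A raised
  cosine rather than a sinusoid keeps the night flat, matching the observed
  night minimum with a distinct daytime peak. An optional smaller dawn bump
  (`dawn_prepeak`, default off) reproduces the early-morning transient that
  appears only intermittently in real recordings.
* **Drought state**: irrigation is a stepwise schedule of levels in [0, 1]
  (fraction of optimal). While the level is below 1, a stress offset `s(t)`
  integrates `-drought_drift_mv_per_day * (1 - level)` per day (default
  5 mV/day at full cutoff) and a deficit exposure `E(t)` integrates
  `(1 - level)` days; the diel amplitude is attenuated by
  `drought_attenuation^E` (default 0.7 per full deficit day). Both rules are
  linear-per-deficit-day phenomenological choices; no functional form is
  established for them. The exposure exponent is continuous rather than
  floored to whole days so the trace stays continuous; at integer deficit days
  the two readings coincide.
* **Rewatering**: at every schedule transition back to level 1.0 the offset
  receives an additional downward `rewatering_spike_mv` (10 mV), after which
  offset and exposure relax exponentially to zero with
  `recovery_tau_hours` (6 h). The recovery form is this package's choice: the
  observed behaviour is a transient downward spike followed by a slow return
  to the pre-stress baseline and rhythm, with no published time constant; a
  single shared exponential is the simplest state model with that shape.
* **Measurement noise** `eta(t)`: Gaussian noise with power spectral density
  proportional to `f^-beta`, synthesized by spectral shaping (white spectrum
  times `f^(-beta/2)`, inverse FFT) and rescaled to `noise_sd`. Defaults
  `beta = 1` (pink), `sd = 2` mV: biological and instrumentation noise floors
  are classically 1/f-dominated at sub-hertz frequencies, and 2 mV leaves the
  15 mV diel bump a 7.5x effect, comfortably above the 5x floor the study
  design calls for. Note one consequence of normalizing the *total* sd of a
  1/f process over a two-week record: roughly 1 mV of it lives at multi-hour
  periods, i.e. in the same band as the dawn/dusk shoulders of the diel bump.

The default sampling rate is 4 Hz. The emulated recording hardware runs at
400 Hz, and that rate remains selectable; 4 Hz keeps a two-week five-plant
simulation at desk scale (24 M samples) while leaving 60 points in the
shortest (15 s) feature window. Timestamps are seconds from the simulation
start internally and ISO-8601 at the I/O boundary. All randomness flows from
one integer seed through `numpy.random.SeedSequence` spawns, so identical
configurations give bit-identical traces.

### What the generator does *not* emulate

Action potentials and variation potentials (the transient signals triggered
by touch, wounding, pruning), electrode-insertion artefacts and drift,
weather-driven day-to-day variation of the diel shape, and coupling between
plants. Passing tests therefore show that the analysis pipeline recovers the
planted diel/drought structure under realistic noise — not that it would
reach the same numbers on real greenhouse recordings.

## Acquisition chain and daily cycles

The recording chain applies a zero-phase (forward–backward) 4th-order
Butterworth low-pass at 30 Hz and band-stop (notch, Q = 30) filters at 50 and
100 Hz. Zero-phase realization is chosen so features are not phase-shifted
relative to the labels. Any filter whose critical frequency reaches Nyquist
is skipped with a logged notice — at the 4 Hz desk rate the whole chain is a
no-op, as intended.

For descriptive analysis the trace is decimated to one point per minute by
within-minute averaging (the mean doubles as the anti-alias step), split into
civil-midnight-aligned 24 h cycles of exactly 1440 points (partial leading and
trailing days dropped), min-max normalized per cycle to [0, 1] (a constant
cycle maps to zeros), and averaged pointwise into a mean ± s.e.m. profile
(s.e.m. = sample sd / sqrt(n), defined as 0 for n = 1 to keep plots total).

## Multi-scale features

Every 5 minutes, seven trailing windows of 15 s, 30 s, 1, 2, 5, 10 and 30 min
share their right edge at the sample time — trailing alignment, so a sample
never uses future data — and 26 features are computed in each window from the
filtered native-rate signal, 182 per sample in total:

| family | features | notes |
|---|---|---|
| statistics | min, max, mean, variance, skewness, kurtosis, IQR | population moments; Fisher skewness and excess kurtosis defined as 0 for constant windows; IQR from linear-interpolation quartiles |
| Hjorth | mobility, complexity | `sqrt(var(dx)/var(x))` and `mobility(dx)/mobility(x)`; 0 on zero-variance denominators |
| Hurst | H(q=2) | structure function `K_q(tau) = <|x(t+tau)-x(t)|^q>` for `tau = 1..min(19, n/10)`; H = log-log slope / q, clipped to [-0.5, 1.5]. H ~ 0 for stationary noise, 0.5 for Brownian motion, 1 for a trend |
| wavelet entropy | Shannon, log-energy | Haar decomposition, `min(floor(log2 n), 8)` levels; Shannon entropy of the subband energy distribution; log-energy sums `ln(c^2)` over all coefficients with a 1e-12 floor |
| noise colour | one-hot over white/pink/brown/blue/purple | slope of log10 PSD vs log10 f (Hann-windowed, mean-removed periodogram, non-DC bins), classified to the nearest target slope {0, -1, -2, +1, +2}; ties go to the smaller magnitude, then white |
| wavelet stats | min/max/mean of db1, db4, db8 detail coefficients | single-level decompositions |

Open readings resolved here: 26 = 7 + 2 + 1 + 2 + 5 + 9 is the only
decomposition consistent with 7 windows x 26 = 182, so the
wavelet-decomposition statistics count inside the 26; "order 1, 4, 8" is read
as Daubechies filter order at a single level (eight *levels* would need >= 256
samples and fail on the 15 s window at desk-scale rates); the Hurst exponent
is computed at q = 2 only. Two per-family minimum lengths are set by what the
estimators need rather than larger conventional values: the Hurst fit needs
>= 20 samples (two lag points) and the noise-colour fit >= 32 samples (15
non-DC periodogram bins), so that all features remain computable in the 60-
sample shortest window at 4 Hz. Below a family's minimum the affected
features are NaN sentinels and such rows are dropped (with a logged count)
before modelling. Feature extraction is vectorised: all windows of one size
form the rows of one array and every family is computed along the last axis,
which keeps a full reference run in minutes on one core.

## Dataset construction

Features are min-max scaled to [0, 1] per plant (`x_nf = (x_f - min)/(max -
min)` within each plant's rows; constant columns map to 0), compensating the
between-plant baseline differences; a global scope is available. Day/night
labels come from the per-day ephemeris with a half-open convention: day iff
sunrise <= clock time < sunset. Drought labels implement a 3-hour onset
delay — a sample is `stressed` iff irrigation has been continuously below
optimal for at least 3 h at the sample time; contiguous deficit segments share
one onset, and returning to full irrigation resets to `normal` immediately
(only the onset rule is established; immediate reset is this package's
choice). Labels are assigned at the sample timestamp (the shared right window
edge), so windows straddling a boundary inherit the label of their edge. The
80/20 train/validation split is uniform at random without replacement
(`ceil(0.8 n)` training rows), unstratified, matching the original protocol;
this ignores temporal autocorrelation between neighbouring samples, so the
held-out accuracy is optimistic relative to a deployment setting — a
`by_day` split that keeps whole plant-days together is provided for
comparison but is not the default.

## PCA exploration

Decimated day cycles are assembled into `X` (1440 minute-rows x one column
per recorded day) for the day/night question and its transpose `Z` (day-rows)
for the water question. The PCA centres columns and, by default, scales them
to unit sample sd (correlation PCA, the common factorial-map practice;
covariance PCA is one flag away because the explained-variance figures depend
on it). Constant columns are dropped with a notice. The decomposition is a
singular value decomposition with a deterministic sign convention (each
component's largest-magnitude loading is positive). Score–raw correlations
are plain Pearson correlations between a component's scores and each original
variable. Group ellipses on the factorial maps are covariance ellipses of the
scores: the chi-squared(2 df, 1-p) contour of each group's mean and
covariance, reported as centre, semi-axes and orientation.

## Classification

Five families: logistic regression, a feedforward multilayer perceptron
standing in for "deep learning" (2 hidden layers x 50 rectified units, early
stopping — no reference architecture is published), a decision tree, a random
forest (200 trees), and gradient boosted trees via XGBoost (200 trees, depth
6, learning rate 0.1; no reference hyperparameters are published). Training
uses only the 182 feature columns — identifiers, timestamps and labels are
excluded by an explicit column check. Metrics are accuracy, precision and
recall as percentages rounded to one decimal, for a stated positive class
that defaults to the majority class of each task (`day`, `normal`);
zero-denominator precision/recall is defined as 0 with a notice. Tree models
report split-gain feature importances normalized to sum to 1 with a
deterministic name tie-break.

## Reference study conditions and problem sizes

The reference synthetic experiment is five plants for 14 days at 4 Hz with
the defaults above and one drought episode: optimal irrigation for 4 days, a
50 % deficit for 2 days, a 36 h cutoff, then rewatering — 20,135 feature
samples, about 58 % day and 24 % stressed. The test suite and the acceptance
script run this experiment end-to-end; smaller configurations (one plant, 2–5
days) back the unit and property tests. These sizes are the package's chosen
desk-scale operating point; the 400 Hz hardware rate and longer runs remain
configuration options.

## Numerical choices and degenerate inputs

Constant windows: variance/skewness/kurtosis/IQR and both Hjorth parameters
are 0, the Hurst exponent is 0, wavelet entropy is 0, the spectral slope is
taken as 0 (hence colour white). Quantiles use linear interpolation.
Explained-variance fractions come from squared singular values of the
centred/scaled matrix. The colored-noise synthesis zeroes the DC bin. Metric
and percentage rounding is one decimal. All estimator classes follow
scikit-learn conventions (`fit`/`transform`, `get_params`, trailing-underscore
fitted attributes) and compose with sklearn model selection.

## Known limitations

* The classifier scores quantify recovery of *planted* structure under the
  generator's assumptions; they are not estimates of real-greenhouse
  performance, and the published accuracies for the motivating experiment are
  not reproducible without its (undeposited) recordings.
* Under the default pink noise, the dawn and dusk shoulders of the raised
  cosine are information-poor (the diel component is below the noise there
  for roughly the first two hours of the day), so day/night accuracy
  saturates well below what near-white noise would allow; misclassifications
  concentrate in 06–08 h and 18–20 h.
* The random split's temporal leakage (above) inflates held-out metrics.
* No artefact rejection beyond non-finite checks; no gap handling.
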