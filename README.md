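# phytoep

Simulation and machine-learning analysis of plant electrical-potential (EP)
recordings.

Plants maintain slow extracellular voltage rhythms — millivolt-scale electric
potentials measured between a petiole electrode and a substrate reference —
that track the day/night cycle and shift when the plant runs short of water:
the baseline drops progressively under deficit irrigation, the daily peak
shrinks, and rewatering evokes a transient downward spike before the rhythm
recovers. `phytoep` is a toolkit for the whole analysis chain that turns such
recordings into physiological status calls, exercised end-to-end on synthetic
data:

* **`phytoep.synth`** — a seeded generator of labelled synthetic EP traces:
  raised-cosine diel cycle (night minimum, afternoon maximum), drought drift
  and peak attenuation driven by an irrigation schedule, rewatering spikes,
  coloured (`1/f^beta`) measurement noise, between-plant baseline variability.
* **`phytoep.preprocess`** — the acquisition chain (zero-phase 30 Hz low-pass,
  50/100 Hz notches) plus 1/min decimation, midnight-aligned 24 h cycle
  splitting, per-cycle min-max normalization and mean ± s.e.m. daily profiles.
* **`phytoep.features`** — the core computation: every 5 minutes, seven
  trailing windows (15 s … 30 min) sharing their right edge are described by
  26 features each — statistics, Hjorth mobility/complexity, the generalized
  Hurst exponent H(q=2), Shannon/log-energy wavelet entropies, a noise-colour
  one-hot from the spectral slope, and db1/db4/db8 detail-coefficient
  statistics — 182 features per sample.
* **`phytoep.dataset`** — per-plant min-max normalization, ephemeris day/night
  labels, drought labels with a 3 h stress-onset delay, class balance,
  80/20 splits.
* **`phytoep.unsupervised`** — PCA factorial maps of the raw day cycles
  (minutes-as-observations and days-as-observations), score–raw correlations,
  p = 0.05 group covariance ellipses.
* **`phytoep.classify`** — LR / MLP ("deep learning") / decision-tree /
  random-forest / gradient-boosted-tree classifiers for day-vs-night and
  stressed-vs-normal, with accuracy/precision/recall and feature importances.

Transform- and model-shaped steps are scikit-learn estimators
(`MultiScaleFeatureExtractor`, `PlantMinMaxScaler`, `FactorialPCA`) and
compose with sklearn pipelines; module-level functions wrap them. See
`docs/methods.md` for the model details and design decisions.

## Worked example

The quickstart pipeline simulates one plant for three days (with a deficit
episode on day 2), extracts and labels features, splits 80/20, trains all
five model families, and writes `dataset.csv`, `report.csv` and
`report.json`:

```sh
$ phytoep run --quickstart --seed 1 --out out/
daynight/LR: accuracy 78.9%
daynight/DL: accuracy 78.9%
daynight/DT: accuracy 91.8%
daynight/RF: accuracy 90.6%
daynight/GBT: accuracy 97.1%
water/LR: accuracy 60.8%
water/DL: accuracy 59.6%
water/DT: accuracy 79.5%
water/RF: accuracy 77.2%
water/GBT: accuracy 84.2%
```

Each line is the held-out accuracy of one model family on one target; the
gradient-boosted trees dominate both tasks, and the drought task is the
harder one — the stress signature (baseline drift, attenuated peak) is
subtler than the day/night swing. `report.csv` adds precision and recall for
the positive class (`day`, `normal`):

```
target,model,accuracy,precision,recall
daynight,GBT,97.1,100.0,94.2
water,GBT,84.2,82.1,95.3
...
```

The same steps are available as library calls (`simulate_traces`,
`extract_features`, `build_labelled_dataset`, `train_models`, `evaluate`)
and as individual CLI stages (`phytoep simulate / preprocess / features /
label / pca / train`).

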