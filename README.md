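# optonose

Analysis pipeline for an optical electronic nose built on liquid-crystal
hybrid-gel sensing films: synthetic signal generation, preprocessing,
per-cycle feature extraction, SVM-based VOC classification, and film-optics
quantification.

The instrument records a single-channel photodiode intensity while a sensing
film cycles through VOC exposure and clean-air recovery (45 cycles of
5 s + 15 s at 90 Hz per assay, duplicate assays, 11 solvent classes, four
film thicknesses). Because no raw recordings are publicly available, the
package ships a first-class simulator that reproduces the acquisition
structure and the qualitative film physics (thicker film → lower baseline
and larger optically active area; logistic rise / exponential recovery
response shapes; slow matrix drift under protic VOCs), so the entire
pipeline is testable offline.

## Modules

| module                  | what it does |
|-------------------------|--------------|
| `optonose.synthetic`    | labeled trace simulation: VOC kinetics library, film set, cycle/assay/experiment generators, CSV + JSON-sidecar serialization |
| `optonose.preprocessing`| sliding-window smoothing (default 100 points), schedule-clocked cycle segmentation, pre-exposure baseline estimation |
| `optonose.features`     | 12 per-cycle features: 9 morphological (amplitude, timing, area, derivative shape) + 3 logistic-fit parameters (A, k, t0) |
| `optonose.classification`| per-thickness RBF SVM (C=100, gamma=0.1), stratified 10-fold CV with per-fold standardization, row-normalized confusion matrices, accuracy/precision reports |
| `optonose.film_optics`  | tilt-corrected thickness (acquired / cos(90 − tilt)), masked mean-gray-value, gray-value time series from image stacks, thickness-trend summaries |
| `optonose.config` / `optonose.pipeline` / `optonose.cli` | YAML run configuration, end-to-end orchestration, command-line interface |

## CLI

```bash
optonose run-all --out results/                 # defaults: full experiment
optonose run-all --config my_run.yaml --out results/
optonose simulate --out traces/                 # trace CSVs + sidecars
optonose features traces/*.csv --out features.csv
optonose classify features.csv --thickness 30 --out report.json
optonose film-optics --acquired-um 30 --tilt-deg 75
optonose film-optics --image film.png --mask 100,100,80
```

`run-all` writes, per film thickness, a feature table (`features_<t>um.csv`),
a row-normalized confusion matrix (`confusion_<t>um.csv`), a metrics JSON
(pooled and fold-mean accuracy, macro precision, per-VOC recall), and a
`manifest.json` with the config hash and seeds. Reruns with the same config
are byte-identical.

An example configuration (all keys optional; shown with defaults):

```yaml
schedule: {n_cycles: 45, exposure_s: 5.0, recovery_s: 15.0, sampling_hz: 90.0}
smoothing: {window_points: 100, window_shape: hanning}
cv: {n_folds: 10, C: 100.0, gamma: 0.1, seed: 0}
noise_sd: 0.3
n_replicates: 2
master_seed: 0
```

## Notes

The default classifier accuracy on simulated data (~0.998 pooled per
thickness) is a property of the simulator's class-separability margin, not a
reproduction of any measured instrument performance.
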