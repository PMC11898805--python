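# hsiq — hyperspectral chemometrics for dried-lily quality

`hsiq` is a tested re-implementation of a hyperspectral screening pipeline
for dried lily bulbs: discriminating sulfur-fumigated from sun-dried
samples and predicting three quality indicators — total polysaccharide
(mg/g), total phenol (mg/g) and SO2 residue (ug/g) — from VNIR/SWIR
reflectance spectra.  It is aimed at chemometricians and food-quality
researchers who want the full chain as reusable, seeded, unit-tested
components rather than a one-off analysis script.

The pipeline:

1. **Calibration** — black/white-plate correction of raw image cubes,
   `R = (R_o - R_b) / (R_w - R_b)`, ENVI I/O, ROI mean-spectrum
   extraction, and fusion of the two sensor grids onto a 396-band working
   grid (410-2500 nm, seamed at 990 nm).
2. **Reference assays** — standard-curve fitting and the content
   formulas `M1 = 5Y/W`, `M2 = 2.5X/W`,
   `M3 = (A - B) · c · 0.032 · 10⁶ / W`.
3. **Wavelength selection** — interval random frog (iRF: a
   reversible-jump pseudo-MCMC chain over interval subsets scored by
   PLS RMSECV) and variable combination population analysis (VCPA:
   binary-matrix-sampled variable combinations, survival of the fittest,
   an exponentially decreasing retention schedule, exhaustive final
   search).
4. **Models** — SVM (RBF / epsilon-SVR) plus three NumPy-implemented
   networks: a 1-D CNN (32- and 128-kernel stride-2 conv blocks), a
   64-unit LSTM, and the CLSTM hybrid in which the conv stack's output
   sequence feeds the LSTM in place of the first fully connected layer.
5. **Evaluation** — stratified splits, accuracy / Pearson R / R² / MAE /
   RMSE, and a leakage-guarded 3 band-group x 4 model benchmark grid.

Because the original field dataset is not deposited, the package ships a
first-class synthetic generator that plants the structure the analysis
assumes: a smooth baseline, one absorption feature per analyte with depth
linear in content, a fumigation signature in the 1200-1400 nm window
scaled by SO2 residue, and seeded per-sample noise.  See
`docs/methods.md` for the model details and what the synthetic results do
and do not demonstrate.

## Worked example

```python
import hsiq
from hsiq.evaluation import (SplitSpec, stratified_split,
                             classification_accuracy, regression_metrics)
from hsiq.models import (ArchitectureConfig, TrainingConfig,
                         build_model, train, predict)

ds = hsiq.simulate_dataset(hsiq.SyntheticConfig(n_samples=400, seed=1))
tr, te = stratified_split(ds, SplitSpec(test_fraction=0.3, seed=1))
tcfg = TrainingConfig(epochs=120, patience=20, min_epochs=50, seed=1)

clf = build_model(ArchitectureConfig(kind="clstm", task="classification"),
                  len(ds.grid), seed=1)
train(clf, tr, "label", tcfg)
labels, probs = predict(clf, te)
print(f"test accuracy: {classification_accuracy(te.labels(), labels):.1f}%")

reg = build_model(ArchitectureConfig(kind="clstm", task="regression"),
                  len(ds.grid), seed=1)
train(reg, tr, "so2", tcfg)
rep = regression_metrics(te.contents("so2"), predict(reg, te))
print(f"SO2 regression: R2={rep.r2:.3f}  MAE={rep.mae:.1f}  "
      f"RMSE={rep.rmse:.1f} ug/g")
```

prints

```
test accuracy: 99.2%
SO2 regression: R2=0.873  MAE=31.9  RMSE=46.7 ug/g
```

i.e. on a 400-sample synthetic study (half fumigated, signature depth
0.1, noise sd 0.02) the CLSTM separates the classes almost perfectly on
the held-out 30% and explains ~87% of the variance in SO2 residue; the
MAE/RMSE are in ug/g on the 100-400 ug/g fumigated range.

The same pipeline is available from the shell:

```bash
hsiq run --config configs/demo.yaml --out runs/demo
```

which simulates a dataset, runs both selectors on the training partition,
trains all four models on Full/iRF/VCPA band groups, and writes
`benchmark.csv`, per-cell prediction dumps, and a SHA-256 manifest; a
rerun with the same config reproduces the dataset and selection hashes
bit for bit.  Other subcommands: `simulate`, `calibrate`, `extract`,
`assay`, `select`, `train`, `predict`.

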