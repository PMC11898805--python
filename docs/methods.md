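# Methods

This note documents the models, the synthetic data they are exercised on,
and the numerical choices made where the design was genuinely open.

## Problem setting

Dried lily bulbs are sometimes processed by sulfur fumigation, which
leaves SO2 residues and degrades nutrients.  The package implements a
hyperspectral screening pipeline: per-sample mean reflectance spectra on a
396-band fused VNIR/SWIR grid (410-2500 nm, sensors seamed at 990 nm) are
used (a) to classify samples as sun-dried vs fumigated and (b) to regress
three reference contents — total polysaccharide (mg/g), total phenol
(mg/g) and SO2 residue (ug/g).

## Reflectance calibration and band fusion

Raw counts are normalised per pixel and band against black (dark-current)
and white (~99% reflectance panel) reference frames,

    R = (R_o - R_b) / (R_w - R_b).

The identity is algebraically exact, so two properties are enforced by
test: frame simulation followed by calibration recovers the generating
spectrum to <= 1e-12, and a common affine transform of all three frames
cancels.  A zero denominator (white == black in any band) is an error
listing the offending band indices — silent NaNs would poison wavelength
selection downstream.  Calibrated reflectance slightly above 1 is normal
against a 99% panel, so values outside [-0.1, 1.5] only log a warning; the
generator clips at 1.05 for the same reason.

Band fusion keeps VNIR bands strictly below the 990 nm seam and SWIR bands
at or above it (the SWIR camera is native at the seam; a flag flips the
convention).  No resampling is performed: all downstream math is
grid-agnostic, so the union grid is the working grid.

## Reference assays

Only the arithmetic of the wet-lab reference methods is implemented:
linear standard curves fitted directly in the absorbance -> concentration
direction (matching how the kit concentration enters the content formulas
and avoiding a divide-by-slope at read time), and the content maps
M1 = 5*Y/W, M2 = 2.5*X/W, M3 = (A-B)*c*0.032*1e6/W.  All three are linear
in their concentration/volume argument and inversely proportional to
sample mass; tests assert the worked examples (50 mg/g, 1.0 mg/g,
48 ug/g) and the scaling laws.

## Synthetic data generator

No public dataset of fumigated-lily spectra exists, so the pipeline is
validated on a generator that plants known structure:

* **Baseline**: offset 0.18 plus three Gaussian humps (amplitude, center,
  width) = (0.45, 700, 350), (0.18, 1500, 320), (0.15, 2200, 260) nm —
  smooth, sample-independent, roughly the shape of dried plant tissue
  reflectance without pretending to be radiative transfer.
* **Analyte features**: one Gaussian absorption dip per analyte with depth
  linear in content — polysaccharide at 1580 nm (4.8e-4 per mg/g), phenol
  at 2120 nm (1.7e-3 per mg/g), SO2 at the signature window (1e-4 per
  ug/g).  Linearity makes content recoverability testable: noise-free,
  each content is an affine function of its feature-band reflectance with
  R² = 1.
* **Fumigation signature**: a raised-cosine window over 1200-1400 nm
  depressing reflectance by `signature_depth * M3 / max(M3 range)` for
  fumigated samples only.  The SO2 analyte dip shares the window, so the
  class signal and the SO2 regression signal are co-located, as the
  screening problem assumes.
* **Contents**: uniform draws (range checks are exact); sun-dried samples
  sit at a constant SO2 floor (5 ug/g).  Defaults: polysaccharide
  50-250 mg/g, phenol 5-60 mg/g, SO2 100-400 ug/g for fumigated samples —
  chosen as plausible magnitudes; the real study never reports its content
  distributions, so these are free parameters of the emulation, not
  estimates.
* **Noise**: additive i.i.d. Gaussian per band (default sd 0.02), clipped
  to [0, 1.05].
* **Seeding**: sample i draws from the stream keyed by (seed, i), so
  datasets are byte-reproducible and growing `n_samples` never reshuffles
  earlier samples.

The study design defaults are 500 samples, half fumigated, signature
depth 0.1.  What passing tests on this generator do **not** show:
robustness to scattering/moisture confounders, baseline drift between
acquisition sessions, spatial texture within a sample, or correlated
noise — real spectra have all four.

## Wavelength selection

Both selectors share a cross-validated fitness: a lean single-target PLS
(NIPALS, components capped at min(10, bands, n - fold size)), scored as
RMSECV for content targets or pooled CV misclassification for the class
target, 5-fold, lower = fitter.  The in-package PLS exists because
selection scores tens of thousands of candidate subsets and per-fit
overhead dominates; it is cross-checked against scikit-learn's
`PLSRegression` in the test suite.

**Interval random frog (iRF).**  The grid is tiled into intervals
(default width 20, step 10).  A pseudo-MCMC chain over non-empty interval
subsets proposes adding or removing one interval per step; a fitter
candidate is always accepted, a worse one with probability
`(current/candidate objective) ** sharpness` clipped to [0, 1].  The
exponent (default 10) is the package's key numerical choice here: CV
objectives of informative vs junk-diluted subsets differ by only a few
percent, and with the plain ratio (sharpness 1) the acceptance is so
permissive that visitation frequencies stay near-uniform and the chain
cannot localise the signature.  Formally the rule is Metropolis sampling
of pi(S) proportional to obj(S)^-sharpness; sharpness 10 maps a ~7% worse
objective to ~50% acceptance.  The chain starts from a small random subset
(inclusion probability min(0.5, 4/m)) and the first 20% of iterations are
discarded as burn-in.  A wavelength's score is the maximum visitation
probability over intervals covering it (overlapping intervals make a mean
ambiguous); the selected set is the union of the `n_keep` most-visited
intervals, frequency ties broken by ascending start index.

**VCPA.**  Each of `n_edf_runs` (default 50) runs draws `n_bms` (default
1000) random combinations of the retained variables (binary matrix
sampling, inclusion probability 0.5, empty rows repaired), scores them,
and computes inclusion frequencies among the best `keep_ratio` (default
0.1) fraction.  The retained pool then shrinks to the count prescribed by
the exponentially decreasing function N_i = round(p * exp(-k*i)) with k
fixed so the last run retains `final_pool` (default 10) variables, keeping
the highest-frequency variables (ties by ascending index).  The final
pool is searched exhaustively (all non-empty subsets, feasible for
<= 14); the fitness-minimising subset wins, ties resolved toward smaller
subsets then lexicographic order.  The trace records the retained count
and the best fitness per run; the schedule is non-increasing by
construction and strictly decreasing whenever the per-run decay exceeds
one variable.

Selection is always computed on the training partition only; the
benchmark verifies this with a fingerprint (SHA-256 of the training X, y)
carried by every `SelectionResult` and refuses leaked selections.  When a
selection returns fewer than 4 bands (possible for aggressive VCPA runs),
the benchmark tops the group up from the selection's own score ranking so
the convolutional models remain buildable.

## Models

All networks are implemented in NumPy with hand-written backpropagation
(gradient-checked layer by layer against central differences).

* **CNN**: input batch-norm -> conv (32 kernels, length 2, stride 2, no
  padding) -> ReLU -> average pool (window 2; skipped when fewer than 4
  positions remain) -> dropout 0.3 -> conv (128 kernels, length 2, stride
  2) -> batch-norm -> ReLU -> dropout -> fully connected 128 (tanh) ->
  output (2 for classification, 1 for regression).  With stride equal to
  kernel length each convolution is a reshape into band pairs followed by
  a matrix product; sequence lengths follow floor-halving
  (396 -> 198 -> 99 -> 49).  ReLU is used after conv/batch-norm and tanh
  on the fully connected layer.
* **LSTM**: 64 hidden units over the spectrum as an ordered band
  sequence, final hidden state into the same 128-wide tanh head.  Feeding
  396 single-band steps is numerically pointless and slow, so the
  spectrum is chunked into 4-band steps (99 steps); the chunk width is a
  config field.
* **CLSTM**: the CNN's convolutional stack unchanged, its 49-step output
  sequence fed stepwise into the 64-unit LSTM, which replaces the first
  fully connected layer.  Conv parameters are shape-identical to the CNN
  and the LSTM width identical to the plain LSTM, so the comparison
  isolates the combination.
* **SVM**: RBF-kernel SVC for classification and epsilon-insensitive SVR
  for regression (scikit-learn), C = 10, standardised inputs.

The LSTM cell follows the standard gate equations
(f, i = sigmoid; g = tanh; o = sigmoid; c_t = f*c_prev + i*g;
h_t = o*tanh(c_t)), with the forget-gate bias initialised to 1.  A
stand-alone `lstm_cell_forward` implements the equations explicitly and
the vectorised layer is tested to match it step for step.

**Training.**  Adam (lr 1e-3), batch 32, cross-entropy or MSE, per-band
input standardisation, regression targets z-scored internally and
de-standardised at predict time (stabilises mixed-unit targets).  Early
stopping watches a 10% validation split (patience 30 by default) but
never fires before `min_epochs` (default 40): cross-entropy on these
spectra routinely plateaus for ~20 epochs before the conv features form,
and stopping inside that plateau returns a chance-level model.  Parameter
snapshots restore the best validation state.  A non-finite loss aborts
with diagnostics.  Everything is seeded; training is deterministic for a
given seed.

## Evaluation

70/30 stratified split (the source study does not state its ratio),
recorded seed.  Classification reports percentage accuracy on train and
test; regression reports Pearson R, R² (the square of R — following the
convention that the quality measure is the squared curve correlation
coefficient), MAE and RMSE.  MAE <= RMSE always; both metric functions
are tested against explicit loop oracles.  The benchmark grid is 3 band
groups (Full, iRF, VCPA) x 4 models under one shared split, every cell
traceable to a stored config, the whole grid bit-reproducible given the
run seed.

## Problem sizes

Validation runs use deliberately moderate sizes: 400-sample datasets
(70/30 split) for model-quality checks averaged over 5 seeds, 200-sample
low-noise datasets for selection recovery over 10 seeds (iRF 300
iterations with `n_keep` = 1 — the planted signature is one contiguous
region; VCPA 25 EDF runs x 200 combinations), and a 120-sample demo
pipeline.  These sizes give stable averages for the properties under
test; the library defaults remain the larger literature-standard values
quoted above.

## Known limitations

* The generator's simplicity means benchmark numbers here say nothing
  quantitative about real lily spectra; only orderings and recoverability
  properties transfer.
* The plain-ratio iRF acceptance rule is available (sharpness 1) but not
  recommended; see above.
* PLS-DA fitness thresholds at 0.5 on a 0/1 coding; heavily imbalanced
  classes would need a different cut.
* SVM checkpointing is not implemented (the baseline refits in seconds);
  network checkpoints are single-file `.npz` archives.
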