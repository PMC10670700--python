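# Methods

`gastronir` implements a Vis-NIR chemometrics workflow for *Gastrodia
elata* quality evaluation: discriminating eleven geographic origins from
400–2500 nm absorbance spectra, and calibrating the contents of six
phenolic constituents (gastrodin GA, p-hydroxybenzyl alcohol HA,
parishins E/B/C/A) plus the composites GA+HA and total.  This note
records the models, the parameter choices and their rationale, the
synthetic data model, and the numerical decisions.

## Workflow

1. **Replicate averaging.** Each sample is scanned three times; the
   arithmetic mean spectrum is used downstream.
2. **Preprocessing.** A Savitzky–Golay second derivative (window 21
   points, cubic polynomial, derivative in per-index units) removes
   baseline offset and slope and sharpens overlapping bands; edge points
   where the filter extrapolates are trimmed, so 1050 recorded
   wavelengths become 1030 features.  Each spectrum is then min-max
   scaled to [0, 1] (SNV is available as an alternative).  The window
   and polynomial order are package choices: the derivative method is a
   field standard, and trimming with window 21 is what reconciles a
   1050-point grid with a 1030-feature model input.
3. **Partitioning.** SPXY — Kennard–Stone max–min accumulation on the
   joint distance `d_x/max d_x + d_y/max d_y` — selects
   `round(0.75 n)` training samples (180 of 240); the remainder is the
   test set.  For classification, y is the integer origin code 1..11;
   for calibration, y is the component being modeled (one split per
   component).  Ties break to the lowest candidate index; if one
   distance term is degenerate (zero spread) the other alone is used.
   The procedure involves no randomness.
4. **Augmentation (training set only).** Each training spectrum is kept
   and 7 perturbed copies are added (total factor 8, 180 → 1440):
   `x'(λ) = x(λ)·β·r(λ) + δ` with β ~ U(0.95, 1.05), a linear ramp r
   from 1 to s ~ U(0.95, 1.05) across the grid, and
   δ ~ U(−0.1·m̄, +0.1·m̄) where m̄ is that spectrum's mean.  Copies
   inherit the parent's label and reference contents — the perturbations
   model instrument and scatter variation, not composition change.  The
   test set is never augmented.
5. **Models.** PLS-DA/PLSR, Euclidean KNN, RBF SVM/SVR with c–g grid
   search, and a 1D convolutional network; all evaluated on the
   untouched test partition.

## Models and their settings

**PLS.** `PLSCalibration` wraps a mean-centered (unscaled) PLS
regression; at full rank it reproduces ordinary least squares, which the
tests verify against a normal-equations oracle.  The component count,
when not fixed, is chosen by 5-fold CV (RMSE for regression, threshold
accuracy for PLS-DA) over 1–20.  PLS-DA regresses a single continuous
response of integer class codes 1..K and assigns the nearest code:
predictions in (k−0.5, k+0.5) map to class k, the boundary k+0.5 to the
lower class, out-of-range values clip to [1, K].  The single-response
coding (rather than one-hot) is deliberate: it matches the published
interval-assignment rule this workflow reproduces.

**KNN.** Euclidean distance, majority vote (classification) or
neighbour mean (regression), default k = 3; k selectable by 5-fold CV
over odd 1–15.  Implemented directly on the pairwise-distance matrix so
two tie rules hold exactly: equidistant neighbours rank by training
index, and a split vote goes to the smallest class code.

**SVM/SVR.** RBF kernel; every (c, g) pair of the grid (default powers
of two, 2⁻⁸…2⁸) is scored by seeded k-fold CV (stratified accuracy /
RMSE), the best pair refit on all data; ties prefer the smallest c then
g.  SVR uses ε = 0.1.  Multi-class handling is the library's
one-vs-one.

**1D-CNN.** The network is implemented in numpy (forward, backward,
Adam) and consists of: train-time Gaussian input noise (σ = 0.05,
absolute); two valid 1-D convolutions (8 then 16 kernels of size 32,
stride 1, ReLU) shortening an L-point input to L−31 and L−62; dropout
0.5; flatten (16·(L−62) = 15 488 for L = 1030); a 128-unit ReLU dense
layer; and either an 11-way softmax head with L1+L2 penalties (both
10⁻⁴) on its weights, or a single linear unit for regression.  Losses
are categorical cross-entropy and MSE.  Inference disables noise and
dropout and is bit-deterministic.  Regression targets are standardized
during training and back-transformed at predict time, which keeps one
learning rate usable across components whose scales differ twenty-fold.

**Optimizer.** Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁷), initial learning rate
0.01, 50 epochs, batch 32.  Two stabilizers are package defaults where
the protocol said nothing more: the learning rate decays ×0.955 per
epoch (0.01 → ~10⁻³ over 50 epochs), and gradients are clipped to
global L2 norm 1.0.  Without them, constant-0.01 Adam steps are large
relative to the second convolution's weights; because its inputs are
non-negative (post-ReLU), a few coherent steps can drive every
pre-activation negative, after which the layer is dead and the network
degenerates to the majority class.  The backward pass is verified
against central finite differences, so this is an optimization
pathology, not a gradient defect; both stabilizers are exposed in
`TrainConfig` and can be disabled.

All stochastic elements — weight init, input noise, dropout, batch
shuffling — derive from one seed, and the pipeline derives its
sub-seeds (data, augmentation, models) from a single run seed.

## Evaluation

Classification reports carry the full confusion matrix and per-class
one-vs-rest TP/TN/FP/FN with precision TP/(TP+FP), recall TP/(TP+FN)
and F1 2TP/(2TP+FP+FN), aggregated with class-support weights.
Support-weighted recall is algebraically the overall accuracy — the
reason published per-model recall columns equal the test accuracy —
and a property test asserts the identity on random confusion matrices.

Calibration reports are R² = 1 − SS_res/SS_tot, RMSE, and the mean
relative error mean(|pred−ref|/ref), tagged `cv` or `prediction`.  The
cv-context statistics (Rv², RMSECV, MRECV) come from 5-fold out-of-fold
predictions on the (augmented) training set; whether a printed training
R² is resubstitution or cross-validated is genuinely ambiguous in this
literature, so both can be computed and the out-of-fold number is the
headline.  MRE requires strictly positive references, which the data
model guarantees.

## Synthetic data model

The study's raw spectra are not publicly deposited, so the package
ships a generator that emulates their statistical structure; every
pipeline stage is tested against it.

* **Design.** Eleven origins with the published per-origin batch counts
  (totalling 240 samples) and published per-origin mean contents of the
  six measured phenolics.  Within an origin, concentrations are
  truncated-at-zero normals with CV 15% — real samples of one origin
  span quality grades, but no within-origin dispersion is published, so
  this is a package choice, exposed as a knob.
* **Forward model.** Beer–Lambert mixing: absorbance is the
  concentration-weighted sum of pure-component absorptivity spectra,
  each a sum of Gaussian bands placed at the overtone/combination
  positions seen in real Vis-NIR spectra of this material (≈980, 1180,
  1420–1440, 1500–1600, 1940, 2150, 2350 nm) with pairwise-distinct
  weight patterns.  Three background constituents (water,
  polysaccharide, visible pigment) have origin-specific mean levels on
  distinct permuted grids; their bands survive derivative
  preprocessing, so the origin signature lives in both composition and
  matrix background — mirroring real averaged spectra that overlap
  tightly yet differ subtly in absorption intensity.  Per-origin smooth
  baseline offset/slope, per-replicate random offset and tilt
  (σ = 0.01), and white noise (σ = 0.002 absorbance) complete the
  model; three replicates per sample.
* **Knobs.** A `separation` factor shrinks all between-origin
  differences toward the grand mean (0 ⇒ origins indistinguishable;
  classifiers collapse toward the 1/11 chance level, which is tested),
  and `noiseless()` returns a pure measured-component mixture with no
  matrix, baseline, scatter or noise — on it, absorbance equals the
  exact linear mixture to 10⁻¹², and PLSR recovers every component with
  test R² ≥ 0.999.
* **What it does not emulate.** Radiative transfer and particle-size
  scattering physics, instrument line-shape, batch/harvest-time
  effects, and any real covariance between composition and matrix.
  Passing tests therefore demonstrate that the pipeline's machinery is
  correct and that the models recover structure the forward model
  encodes — not field performance on real tubers.

## Problem sizes and runtimes

The default conditions reproduce the study's: 240 samples × 1050
wavelengths, 3:1 SPXY split, factor-8 augmentation (1440 × 1030 training
matrix), 50-epoch CNN training.  One CNN training takes roughly 2–3
minutes on a single CPU core; the hot loops (im2col/col2im, the fused
Adam update) are numba-compiled with a numpy fallback.  Model-selection
searches in the orchestrated pipeline default to modest grids
(documented in `RunConfig`) and are fully configurable.

## Known limitations

* PLS-DA with single-response integer coding degrades when many classes
  are not ordered along one spectral direction; this is inherent to the
  coding rule being reproduced, not to the implementation.
* The CNN's stability at learning rate 0.01 depends on the stabilizers
  described above; disabling both reproduces the published settings
  literally but fails to train for many seeds on the synthetic data.
* Between-origin concentration structure is anchored to published
  means; absolute classification accuracies on synthetic data depend on
  the chosen matrix-background separation and should not be read as
  field estimates.
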