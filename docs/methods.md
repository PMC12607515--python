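# Methods

This note documents the models and procedures implemented in `milletnir`,
the parameter choices that matter, and what the synthetic data generator
does and does not emulate.

## Reflectance calibration and ROI geometry

Raw counts are converted to reflectance per band (and per pixel, if
per-pixel reference images are supplied) as `R = (R0 − Rb)/(Rw − Rb)`.
Calibration frames may be full images or per-band vectors; the per-band
form is the default and is what the synthetic cube generator emits. Any
band (or pixel) where white equals dark raises an error naming the
location rather than producing silent infinities. Calibrated reflectance
is deliberately **not** clipped to [0, 1]: clipping would destroy the
affine structure that SNV later relies on, so artifact handling is left to
preprocessing.

The ROI is an ellipse in image coordinates: center `(row, col)`, semi-axis
`a` along columns and `b` along rows, an integer stride subsampling the
lattice on both axes. Pixels satisfying `((r−r0)/b)² + ((c−c0)/a)² ≤ 1`
are enumerated left-to-right, top-to-bottom (row-major), matching the scan
order of the acquisition program; the mean over the ROI pixels is the
sample's spectrum. Degenerate axes select only the center line or pixel.
Coordinates are 0-based throughout.

The modeling window is the closed interval [950, 1650] nm. The default
wavelength grid is 148 evenly spaced bands across that window. A real
172-band instrument grid at 4.715 nm spacing over 900–1700 nm does not
reduce to exactly 148 bands by windowing alone, and instrument grid
definitions vary, so the grid is fully configurable; the 148-band count is
guaranteed only on the default grid.

## Preprocessing chain

Order: Savitzky–Golay → airPLS → SNV, each applied per spectrum.

* **Savitzky–Golay** (window 5, polynomial order 1 by default): local
  least-squares polynomial smoothing; edges are handled by evaluating the
  polynomial fitted to the terminal windows, so any global polynomial of
  degree ≤ the filter order passes through unchanged. A `sg_frame_length`
  field is accepted for config compatibility but the filter is fully
  determined by window and order; with order 1 and a symmetric window the
  filter is a moving average.
* **airPLS** (λ = 10⁴, 2nd-order difference penalty, ≤800 iterations):
  the baseline z minimizes `Σ w_i(x_i − z_i)² + λ‖D²z‖²` with weights
  re-estimated each iteration — points at or above the baseline get weight
  0, points below get `exp(t·η·|x_i − z_i|/‖d⁻‖₁)` with `η` the weight
  exponent (0.1) and `d⁻` the negative residuals. Iteration stops when
  `‖d⁻‖₁ < ρ·‖x‖₁` with `ρ` the negative-deviation ratio (default 0.05).
  The endpoints keep unit weight so the penalized system stays anchored.
  Note on the stop ratio: at the default 0.05 the iteration stops early
  and the baseline under strong peaks is recovered to roughly 7 % RMS
  off-peak; tightening the ratio to the canonical 0.001 lets the reweighting
  reach its fixed point and recovers a known baseline to well under 2 %.
  Both values are exposed in `PreprocessConfig`; the oracle tests use the
  converged setting where the fixed point is the point of the check.
* **SNV**: `(x − mean)/sd` with the n−1 denominator, per spectrum. A
  zero-variance spectrum is an error, not a silent NaN.

Because every stage is a per-spectrum map, the chain can be applied before
the train/prediction split without information leakage.

## CARS wavelength selection

Implemented exactly as the five-step loop described in the README, with
these documented choices where the procedure is under-specified:

* Forced-retention counts use the ceiling of `r_j · p`.
* ARS is weighted sampling **with replacement** followed by deduplication
  (the canonical form of the "survival of the fittest" step); the forced
  retention and the ARS draw both target `⌈r_j·p⌉`.
* The inner PLS component count is `min(10, |subset|, n_train − 1)`;
  10 is a configurable cap.
* RMSECV is computed on the full calibration set passed to `run_cars`,
  not on the 80 % Monte Carlo draw, with folds assigned by a seeded
  shuffle (seed + iteration index), so the whole trace is reproducible.
* Ties in the RMSECV trace resolve to the earliest iteration (larger,
  more conservative subsets appear earlier).
* If a fit degenerates to all-zero coefficients the kept set falls back
  to uniform weights; a subset can never shrink below one wavelength.
* The inner PLS is an in-package numpy SIMPLS, used because a CARS run
  performs thousands of fits; it is cross-checked against scikit-learn's
  `PLSRegression` in the test suite, and the model back-ends use
  scikit-learn directly.

`run_cars_repeated` re-runs the whole procedure under consecutive seeds
(50 by default) and reports the run with the lowest RMSECV, mirroring the
repeated-run protocol used for the regression models.

## Regression back-ends

All four models share a fit/predict contract, standardize internally
(PLSR centers; the others scale features and target), and return
predictions on the original target scale.

* **PLSR**: scikit-learn `PLSRegression`; the component count is selected
  by seeded k-fold cross-validation (smallest count on ties).
* **SVR**: RBF kernel; any of C, ε, γ left unset is tuned by seeded
  5-fold grid search over C ∈ 10^{−1..3}, ε ∈ 10^{−4..−1}, γ ∈ 10^{−3..1}
  (the ε grid applies to the standardized target).
* **CNN**: one 1-D convolution block (8 channels, kernel 3, valid
  padding), ReLU, flatten, linear head; below three input features a dense
  ReLU layer replaces the convolution. The head is zero-initialized so the
  initial predictor is the training mean.
* **BiLSTM**: the wavelength axis is read as a scalar sequence by one
  forward and one backward LSTM (hidden size 16, forget-gate bias 1);
  final hidden states are concatenated into a linear head.

The two networks are small numpy implementations with exact manual
gradients, trained full-batch with Adam, initial learning rate 0.01
decayed ×0.2 every 100 epochs, L2 coefficient 0.01 on weights (not
biases), global gradient-norm clipping at 1, a 5000-epoch cap and early
stopping after 200 epochs without training-loss improvement (best
parameters restored). The architectures themselves are deliberately
minimal design choices sized for 3–148 inputs and ~160 training samples;
the training hyperparameters are the recipe the pipeline standardizes on.
Seeded initialization plus deterministic numpy arithmetic makes training
bit-reproducible.

## Evaluation conventions

* **Split**: `|train| = round(0.75 n)` (217 → 163/54), seeded shuffle.
* **Metrics**: `R² = 1 − SS_res/SS_tot`, `RMSE = √(SS_res/n)`,
  `RPD = sd(y_true)/RMSE`. RPD uses the population (denominator-n) SD by
  default because that convention makes `RPD = (1 − R²)^(−1/2)` an exact
  identity on a same-set evaluation; the sample-SD variant is available by
  flag. Perfect predictions report `RPD = +inf`. Interpretation bands:
  `> 2` good, `(1.4, 2]` moderate, `≤ 1.4` unable.
* **QC**: per-analyte Shapiro–Wilk at α = 0.05 and 1.5·IQR boxplot
  flags; the report never removes samples.
* **Repeated-run protocol**: each run re-splits, optionally re-runs CARS
  on its training set, fits the requested models and scores both sets.
  The reported run maximizes prediction-set R² by default (criterion
  configurable), and the full per-run distribution is always retained so
  the selection optimism is visible. Per-run failures are recorded and do
  not abort the protocol.

## The synthetic data generator

Chemistry: n samples (default 217) from a multivariate normal truncated at
zero. Default means are a typical essential-amino-acid composition of
millet protein (percent of total protein; Ile 12.94 … His 1.787, summing
to 38.94). No public per-sample covariance exists for such data, so the
defaults use a 5 % coefficient of variation per analyte — plausible for a
single variety from one site — and a uniform 0.3 inter-analyte
correlation; both are parameters. Marginals are normal by construction,
which is what the downstream Shapiro–Wilk QC expects.

Spectra: log10 Beer–Lambert mixing. Each component contributes
`concentration × Σ amplitude·gauss(λ; center, width)` to absorbance; the
default library places Gaussian bands (width 10 nm, amplitude 0.03 per
concentration unit) at each amino acid's informative wavelengths, plus a
moisture band at 1450 nm and a carbohydrate band at 1200 nm whose
concentrations vary per sample — these interferents mask the
low-concentration analytes (Lys, His) the way real grain matrices do. The
band width/amplitude defaults are set so that, noise-free, an analyte's
content correlates strongly (r > 0.8) with absorbance at its own band
center despite neighboring-band overlap — the structural property the
wavelength selector exploits. Reflectance is
`gain·10^(−A) + offset + ε` with per-sample log-normal gain (σ = 0.05),
additive offset (sd 0.01), a slow polynomial absorbance drift, and i.i.d.
sensor noise (sd 0.003) — exactly the artifact classes SNV, airPLS and
S–G are designed to remove.

Cubes: `generate_cube` inverts the white/dark calibration with smooth
band-dependent reference vectors, tiling each sample's spectrum into a
rectangular patch, so the instrument-I/O stage round-trips end to end.

What the generator does **not** emulate: nonlinear matrix effects
(scattering–absorbance coupling, Kubelka–Munk behavior), batch/session
drift, wavelength-calibration error, or the true covariance of any real
cultivar. One consequence is worth stating plainly: because the forward
model is linear and the calibration set (163 samples) exceeds the band
count (148), a cross-validated full-spectrum PLSR is close to optimal on
this data, so restricting models to CARS-selected wavelengths matches but
does not systematically beat full-spectrum accuracy here. On real grain
spectra the opposite is repeatedly observed; reproducing that gap requires
exactly the non-ideal effects listed above. Passing tests therefore
demonstrate the pipeline's correctness and the selector's ability to
recover genuinely informative bands, not a universal accuracy advantage of
wavelength selection.

## Problem sizes used in the test suite

Statistical properties are checked at sizes chosen to make the suite a
routine desk run: CARS recovery uses 50 seeds at N = 200 iterations
(n = 217, p = 148); the protocol comparison uses 20 runs per mode with
PLSR; network capacity checks use ≤ 200 samples and ≤ 5 features. The
pipeline defaults (N = 500, 50 runs, 10-fold CV) remain the standard
configuration for actual use.
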