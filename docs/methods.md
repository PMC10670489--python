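# Methods

## The analysis problem

A Raman micro-spectrometer focused on a cell nucleus records inelastic
scattering as intensity versus Raman shift (cm⁻¹).  In the 600–1800 cm⁻¹
fingerprint region the spectrum superposes: (i) pseudo-Voigt-like
vibrational bands of nucleic acids, proteins, lipids and carbohydrates;
(ii) a smooth, much larger fluorescence background; (iii) detector noise;
and occasionally (iv) corrupted content — cosmic-ray spikes or
fluorescence bursts.  Tumor (HCC) nuclei carry more nucleic acid than
non-tumor hepatocyte nuclei, which raises the DNA/RNA bands (782–785,
1094, 1335, 1370, 1578 cm⁻¹) and, relatively, lowers the Amide III band
near 1240 cm⁻¹ and the CH₂/CH₃ deformation at 1438 cm⁻¹.  The package
estimates the class of each spectrum, and from spectrum-level votes the
tumor fraction of a blind cell mixture.

## Synthetic-data generator (`synth`)

The generator defines the study conditions under which everything is
tested.

- **Design**: 40 cells per class × 5 spectra per cell (the acquisition
  layout of a realistic single-cell campaign), axis 600–1800 cm⁻¹.
- **Lineshape**: pseudo-Voigt with Gaussian/Lorentzian mix η = 0.5, a
  standard and flexible choice for condensed-phase Raman bands.  One band
  per canonical fingerprint assignment (22 bands), with FWHM 8–20 cm⁻¹
  and relative amplitudes chosen so the phenylalanine 1004, CH₂/CH₃ 1444
  and Amide I 1656 cm⁻¹ bands dominate, as in measured cell spectra.
- **Class contrast**: amplitude multipliers 1.25 on the five
  nucleic-acid bands (elevated in Tumor) and 0.80 on 1240/1438 cm⁻¹
  (elevated in Non-Tumor).  These magnitudes put the class-mean
  difference at a few percent of the tallest peaks — large enough to be
  recoverable, small enough that plain LDA on raw channels overfits.
- **Fluorescence baseline**: random cubic polynomial, 1–4 a.u. offset
  (several times the peak heights) — removable exactly in expectation by
  an order-3 polynomial fit.
- **Cell heterogeneity**: one log-normal factor per cell (σ = 0.25)
  multiplying the class-informative band amplitudes, emulating the
  intra-/inter-cell variability of primary (uncultured) cells that makes
  spectra from the same cell correlated.
- **Noise**: additive Gaussian, σ = 0.08 a.u. (~8% of the tallest band).
  Together with the heterogeneity this was calibrated once so that plain
  LDA lands in the mid-90% accuracy range and tuned models above it —
  a solvable-but-nontrivial regime; real patient data are harder still
  (see Limitations).
- **Corruption (outliers)**: a configurable fraction of spectra
  (default 10% in the study workflow) receive either a narrow 12× spike
  (cosmic ray) or a 10× fluorescence baseline **with its shot noise**
  (σ = 0.08·√(relative intensity)).  The shot-noise term matters: the
  smooth part of a fluorescence burst is removed exactly by baseline
  correction, so without it that corruption mode would be undetectable
  downstream — physically, a saturated fluorescence channel is noisy, not
  clean.
- **Mixtures**: cells mixed at chosen Tumor:Non-Tumor ratios with labels
  hidden (ground truth retained in metadata only).

What the generator does **not** emulate: instrument line-shape functions,
CCD etaloning, wavelength-dependent sensitivity, cosmic-ray statistics,
water/substrate bands, biological covariance between bands beyond the
single heterogeneity factor.  Passing tests therefore demonstrate that
the pipeline recovers structure *of the kind assumed*, not clinical
performance.

## Preprocessing (`preprocess`)

Fixed order: rigid axis calibration against the 520.7 cm⁻¹ crystalline-Si
line (translation only; a single reference line cannot constrain
dispersion) → linear-interpolated substrate background subtraction →
crop to the closed interval [600, 1800] cm⁻¹ → baseline correction →
vector normalization to unit Euclidean norm (the standard chemometric
reading of "vector normalization").

Baseline correction is the modified-polyfit iteration: fit an order-3
polynomial, clip the working signal to the fit (progressively excluding
peaks), repeat until the relative change of the baseline < 1e-4 or 100
iterations.  On a peak-free polynomial of degree ≤ 3 the first fit is
already exact.  The tolerance default is 1e-4 because the clipping
iteration's relative change plateaus near 1e-6 without ever crossing it
on realistic spectra; at 1e-4 the fit converges in ~30–60 iterations with
a corrected-versus-true-peak correlation of 0.9995 on simulated input.
Non-convergence warns rather than fails.

## Outlier screening (`qc`)

PLS1-DA (one response column, Non-Tumor = 0 / Tumor = 1; 5 latent
variables by default — small relative to n, enough for the
class-relevant variance) fitted to the preprocessed spectra.  Per
spectrum: Q = ‖x-residual‖² and T² = Σₐ tₐ²/s²ₐ over the A score
columns.  Limits at 95% confidence: Jackson–Mudholkar approximation from
the residual eigenvalues for Q; A(N−1)/(N−A)·F₀.₉₅(A, N−A) for T².
Spectra exceeding either limit (rule "either", the conservative
screening choice; "both" is available) are flagged, once, before any
classifier sees the data.

Screening runs on *preprocessed* spectra (the pipeline order is
preprocess → QC → modeling), which has one important interaction with
corruption: a smooth fluorescence burst is removed by baseline
correction, and a single dominant spike direction can be absorbed into a
latent variable ("masking"), leaving a near-zero Q but an extreme T².
The union rule is what makes screening robust to both effects; at the
default study scale (400 spectra, 10% corrupted) detection is complete
with a sub-1% false-flag rate, and the retained counts (~180 per class)
match the bookkeeping a real campaign of this design reports.

## Chemometric classifiers (`chemometrics`)

- **PCA** on the covariance matrix of the mean-centered intensity
  matrix, eigendecomposition route, components sorted by decreasing
  variance.  Explained-variance percentages sum to 100.
- **LDA**: linear discriminant with empirical priors
  (`sklearn.discriminant_analysis` behind a uniform
  predict/confidence wrapper).
- **Tuned LDA**: exhaustive grid over the standard tunable surface —
  solver ∈ {svd, lsqr, eigen}, shrinkage ∈ {none, auto, 0.1…0.9},
  priors ∈ {empirical, uniform} — scored by stratified k = 5 CV
  accuracy; ties break first-in-grid; infeasible configurations (eigen
  solver without shrinkage on singular scatter) score −∞.  Shrinkage is
  what rescues LDA in the p ≫ n regime of full-resolution spectra.
- **PCA-LDA**: leave-one-out CV of LDA on the leading principal
  components, count scanned over 5–60 (step 5 in the study workflow,
  step 1 supported); smallest count on ties; the cumulative explained
  variance of the selection is reported alongside.
- **Learning curve**: train/CV accuracy versus training-set size with a
  stratified subsample per fold.
- **Metrics**: confusion counts with Tumor as positive class;
  sensitivity = TP/(TP+FN), specificity = TN/(TN+FP); percentages
  reported to 2 decimals.
- **Splits**: stratified spectrum-level 80/20 by default, mirroring the
  usual practice; a cell-grouped split is provided because spectrum-level
  splitting leaks cell identity between train and test (five spectra per
  cell are correlated) and is the more honest protocol for per-cell
  claims.

## CNN-LSTM (`deep`)

Implemented in NumPy with explicit backpropagation (the analytic
gradients of every layer and of the selective objective are verified
against central finite differences in the test suite).

- **Windowing**: kₛ = 3 contiguous, non-overlapping, equal slices;
  trailing points beyond a multiple of kₛ are dropped (at 1 cm⁻¹
  resolution that is 1 point of 1201 — a negligible, deterministic rule).
- **2-D kernel on 1-D data**: each slice is reshaped to an 8-row patch
  (columns = slice length / 8) so the stated 6×4 convolution kernel
  applies; 'same' padding, stride 1.  The row count 8 keeps ≥ 6 rows for
  the kernel while preserving locality along the axis.
- **Architectures**: named by total layer count over a documented
  manifest that counts every named layer (input, window wrapper, conv,
  activation, pooling, dropout, dense, softmax, selective and auxiliary
  layers).  The 25-layer network has three conv stages (one convolution
  each, filters f₁,f₂,f₃); the 56-layer network has four stages of four
  convolutions each plus per-stage dropout.  Behavior, not the count, is
  the tested contract; the deeper build strictly dominates in parameter
  count.
- **Sequence head**: flatten per slice → 100-unit LSTM over the 3-slice
  sequence → dropout 0.5 → dense + ReLU → tuned dropout → 2-way
  softmax.
- **Selective (reject) branch**: two dense layers on the LSTM state
  producing a confidence g ∈ [0,1]; SelectiveNet-style objective —
  confidence-weighted selective risk + λ·max(0, c − coverage)² with
  λ = 32 and target coverage c = 0.9, averaged 1:1 with an auxiliary
  cross-entropy head.  Prediction rejects iff g < threshold (0.2/0.8 are
  the reference operating points).  When the reject option is off the
  network trains with plain cross-entropy and confidence falls back to
  the softmax maximum.
- **Augmentation** (training folds only, never validation/test —
  enforced by instrumentation the tests assert on): per window, a single
  multiplicative intensity factor in ±10%, and/or a frequency-axis shift
  of up to ±10% of the window length with boundary-value padding.
- **Training**: Adam (batch 32), stratified k = 5 CV, early stopping on
  validation loss (patience 15 by default).  Per-fold
  precision/recall/F1 exclude rejected spectra.
- **TPE**: the tuned surface is layer count {25, 56}, learning rate
  log-uniform [1e-4, 0.05], dropout [0.1, 0.25], reject threshold
  {0.2, 0.8}, augmentation mode {none, frequency, value, both}.  The
  optimizer is a standard Tree-structured Parzen Estimator: after a
  random start-up phase, trials are split at the γ = 0.25 quantile,
  good/bad densities are estimated per parameter (Gaussian KDE for
  continuous, add-one counts for categorical), and the candidate
  maximizing log l(x) − log g(x) is evaluated next.
- **Ablation**: the 16-row grid 2 architectures × 2 reject thresholds ×
  4 augmentation modes, each scored by CV precision/recall/F1 (the F1
  column is always the harmonic mean of the other two).

## Blind mixtures (`evaluate`)

Spectrum-level vote counting: the estimated tumor percentage is
100·(Tumor votes)/(non-rejected votes).  Its large-sample limit is
p·sens + (1−p)·(1−spec) for true tumor fraction p — the estimator is
biased unless sensitivity = specificity = 1, which is why mixture
estimates track nominal values only as closely as the per-class
accuracies allow.  A preprocessing-configuration hash stored with every
pipeline output guards against scoring a blind set preprocessed
differently from the training data.  A per-cell majority-vote aggregation
is deliberately left out of the default path (votes are per spectrum).

## Problem sizes used in the shipped study

`workflows.run_synthetic_study` — the function the acceptance script and
the end-to-end tests run — uses: axis step 2 cm⁻¹ (601 points), CNN
filters (8, 16, 32) instead of the reference (64, 128, 256), epochs ≤ 80
with patience 10, and the 5-step PC scan.  These sizes keep the complete
study to a few minutes on a single core while exercising every stage at
full structural fidelity; the reference filter counts remain the
configuration default for the architecture itself.

## Known limitations

- Synthetic spectra are far better behaved than patient data; the
  accuracies reported on them (high 90s) characterize the pipeline, not
  the clinical problem (where ~90% is a strong result).
- The default spectrum-level splits leak cell identity; use
  `split_mode="cell"`/`cell_split` for per-cell claims.
- The Q statistic is vulnerable to masking by single dominant outliers;
  the union rule with T² mitigates but robust estimators are out of
  scope.
- The mixture estimator is the raw vote fraction; no bias correction by
  estimated sensitivity/specificity is applied.
- Training determinism is exact under a fixed seed on a given NumPy
  build; across BLAS builds small numeric drift is possible.
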