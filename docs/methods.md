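# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical conventions.

## ECG processing chain

The QRS detector is the classic Pan–Tompkins design: cascaded low-pass and
high-pass integer-coefficient filters, a five-point derivative, squaring,
and moving-window integration, followed by adaptive thresholding.

**Coefficients.**  Two selectable coefficient sets exist for the high-pass
and derivative stages (`coeffs="canonical"`, the default, and
`coeffs="paper"`, a variant sign pattern found in some transcriptions of
the filters).  The canonical high-pass is all-pass-minus-low-pass and has
DC gain exactly 0; the variant does not, and diverges on a DC input — both
are kept selectable so either convention can be tested, but all defaults
and all oracles use the canonical set.

**Sampling rate.**  The integer-coefficient filters are designed at
200 Hz.  The package applies them at the signal's native rate (the
screening hardware this chain models samples at 350 Hz) and logs a warning
when fs ≠ 200 Hz; resampling is deliberately not performed by default,
because the windows that matter downstream (150 ms integration, 120 ms ST
segment) are specified in milliseconds and converted at the native rate.
All ms→samples conversions use half-up rounding,
`W = ⌊ms · fs/1000 + 0.5⌋`, so 150 ms at 350 Hz is 53 samples (a stated
tie-break is needed for 52.5).

**Filters are causal with zero initial state**; out-of-range history terms
are zero.  Consequences: the first ~45 samples of the linear chain are
transient and all steady-state statements (DC gain 36 for the low-pass, 0
for band-pass and derivative) apply only after the memory fills.  The
chain is exactly linear up to the squaring stage, which the property tests
exploit.

**Thresholding.**  The detector keeps running signal- and noise-level
estimates S and N over the integrated signal, initialized as its maximum
and mean over the first 2 s, with threshold `T = N + 0.25(S − N)` and the
standard 1/8 exponential update on each classified local maximum.
Candidates must be ≥ 200 ms apart (refractory period).  Accepted
candidates are mapped back to the raw timeline by searching for the raw
maximum in `[c − D − 60 ms, c]`, where `D = 5 + 16 + 2 + (W−1)/2` samples
is the cumulative group delay of the linear stages plus the integration
window's half-width.  Signals shorter than the 2 s initialization span are
rejected; a signal with no threshold crossings returns an empty peak set
(not an error).

## ST segment and derived features

The ST segment defaults are expressed in milliseconds — 57.14 ms offset,
120 ms length — chosen so that a 350 Hz signal reproduces exactly the
20-sample offset and 42-sample length used by the hardware pipeline this
models, while other sampling rates remain meaningful.  The slope is
`(X − Y)/N` with N the sample count (not N − 1, matching the printed
formula this reproduces); it is invariant to constant offsets.  Per
recording the mean over beats is reported (median by flag; the aggregation
was unspecified upstream, mean is declared here).  The mapping of the
continuous slope onto the ordinal `slope` attribute uses a ±0.002
units/sample flat band — a declared default, not an inferred one, since no
published mapping exists; it is configurable.

`oldpeak` (SVR) and `restecg` (SVC) completion select predictors by
Pearson correlation with the target at a default threshold |r| ≥ 0.2
(configurable; the upstream description says correlations were analyzed
but states no cutoff).  Oldpeak predictions are clipped to the overlap of
the observed training range and the attribute's hard 0–6.2 domain.
`thalach` is defined as the maximum of exactly 20 consecutive pulse-rate
readings; out-of-range readings (default bounds 30–250 bpm) raise in
strict mode or are clamped with a warning otherwise.

## Preprocessing recipe

- **MICE**: a single completed dataset (m = 1), default 10 iterations of
  per-column regression imputation with a convergence tolerance, seeds
  explicit.  Observed values are never altered; imputed categorical values
  are snapped to the nearest value of their domain.  A column with no
  observed value is a configuration error.
- **Robust scaling**: `(x − median)/IQR` per continuous column; the fitted
  state (medians, IQRs) is retained and re-applies exactly to new records.
  Zero-IQR columns are centered only, with a warning.
- **Encoding**: categorical attributes map to 0..K−1 by fixed
  domain-order dictionaries (e.g. chest-pain type 1..4 → 0..3), invertible
  via the retained encoder state.  Unseen categories are errors naming the
  column and value.
- **Oversampling**: plain random duplication with replacement of
  minority-class records up to the majority count; originals are always
  retained.  A synthetic-interpolation variant is out of scope.
- **Split**: |train| = round(0.7 n), optionally stratified (per-class
  proportions preserved within one record).

**Order.**  The default order oversamples *before* the 70/30 split,
reproducing the upstream recipe faithfully — but this duplicates records
across the split and inflates test scores, so the pipeline logs a
prominent warning and offers `split_first=True` (CLI `--split-first`) for
the leakage-free order.  The held-out properties in the test suite all use
the leakage-free order.

## Stacking classifiers

Meta-features are out-of-fold class-probability vectors from stratified
k-fold (default 5) cross-validation on the training set; the
logistic-regression meta-classifier is fit on these, and base learners are
then refit on all training data.  Out-of-fold stacking is chosen
deliberately: fitting the meta-learner on in-sample base predictions leaks
the training labels, and that variant is not offered.  Ten base learners
are available (KNN, Gaussian naive Bayes, random forest, SVM, gradient
boosting, SGD with log loss, XGBoost, MLP, decision tree, AdaBoost), each
exposing predict_proba.  Default stacks: {KNN, XGB, MLP} for two zones,
{SVM, KNN, XGB} for three.  The combination search evaluates every
size-3/4/5 subset of five candidates — C(5,3)+C(5,4)+C(5,5) = 16 models —
and ranks them by held-out macro-F1.

Hyperparameter grids are unpublished upstream; modest declared grids
(neighbor counts, tree depths, regularization strengths, hidden-layer
sizes) live in `DEFAULT_GRIDS` and the full search trace is serialized.
Grid search scores by macro-F1.  Probability ties in prediction break to
the lowest class index.

**Metrics** are macro-averaged (unweighted mean over classes) from the
confusion matrix; per-class metrics with zero denominators are defined as
0 with a warning.  ROC-AUC is one-vs-rest per class via the midrank
Mann–Whitney statistic; a class absent from the truth reports NaN.  The
macro convention is validated by exact reproduction of the two-level
field-evaluation matrix statistics (accuracy 90 %, macro precision
90.7 %, recall 88.5 %, F1 89.3 %).  Note the three-level matrix yields
macro recall 90.7 % and macro F1 86.7 %; no averaging convention (macro,
micro, or support-weighted) reproduces the upstream-quoted 91 % / 87.7 %
for that matrix, so those two numbers are not asserted anywhere.

## Synthetic generators

**ECG.**  Each beat is a sum of Gaussian bumps for P, Q, R, S, T at fixed
fractional offsets of the RR interval (amplitudes 0.12, −0.12, 1.0,
−0.15, 0.28; R amplitude normalizes the scale), plus a linear ramp of the
requested slope across the 57–177 ms post-R window and optional white
noise.  Ground truth (R indices, injected slope) is emitted alongside.
Beats are strictly periodic.  This exercises QRS detection and ST
measurement in closed form; it does **not** emulate arrhythmias, RR
variability, baseline wander, electrode-motion artifacts or device noise
spectra — passing detection tests here demonstrates correctness of the
algorithmic chain, not clinical-grade robustness.  At heart rates above
~80 bpm the T wave begins to intrude into the fixed-ms ST window (as it
does physiologically), so slope-recovery oracles run at 60 bpm where the
window is clean.

**Cohort.**  Labels are drawn from the requested class proportions
(default: the 413/258/249-of-920 three-zone tally); continuous attributes
are class-conditional normals with marginal means/SDs matching the
clinical table (age 54 ± 9 y, resting BP 131 ± 18 mmHg, cholesterol
250 ± 52 mg/dl, max heart rate 150 ± 23 bpm, ST depression 1.05 ± 1.14),
means separated by `effect_size` pooled SDs along clinically plausible
directions (risk ↑ with age, BP, cholesterol, ST depression; ↓ with max
heart rate), truncated to the attribute ranges.  Categoricals mix a
"healthy" and a "diseased" distribution with a severity- and
effect-size-dependent weight.  Missingness is MCAR by default (exact cell
count, never blanking a whole column); a MAR mode tilts masking toward
older records.  The generator produces idealized class structure — real
UCI data has correlated features, site effects and non-normal marginals —
so held-out scores on it validate the pipeline mechanics, not the
achievable clinical accuracy.

## Problem sizes and determinism

Recovery and performance properties run at desk scale: 60-beat ECG
fixtures, cohorts of 200–600 records, 16-model combination searches over
the five cheapest learners.  These sizes are where the properties asserted
(100 % detection on clean fixtures, ≤ 15 % slope error, ≤ 5 % MICE error,
macro-F1 ≥ 0.95 at 3-SD separation) are already stable; larger inputs
change runtimes, not conclusions.  Every stochastic component (generators,
imputer, resampling, splits, learners) takes an explicit seed, and
fixtures regenerate bit-identically from their parameter tuples, so tune →
stack → evaluate is deterministic end to end.

## Known limitations

- Single-lead ECG only; no arrhythmia handling, no real-time streaming.
- The ST slope is a unitless amplitude-per-sample measure on the raw
  signal; no isoelectric-line-referenced ST deviation in mV is computed.
- The categorical-slope thresholds and the oldpeak completion target the
  dataset's scales; they are declared conventions, not clinically
  validated calibrations.
- The default (recipe-faithful) oversample-then-split order leaks
  duplicates into the test set; use `split_first=True` for honest held-out
  scores.
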