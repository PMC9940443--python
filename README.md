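# cardiorisk

Cardiovascular-disease (CVD) risk screening from wearable-grade inputs: a
single-channel ECG, a pulse-rate sequence, and a handful of clinical
attributes.  The package implements the full computational chain of such a
screening system — ECG feature extraction, completion of features that
would otherwise require an exercise test, a tabular preprocessing recipe,
and stacking-ensemble classifiers that map a 12-attribute record onto
traffic-light risk zones — together with synthetic generators and
evaluation utilities so the whole chain is testable without any data
download.

It is aimed at researchers and engineers prototyping ML-based cardiac
screening pipelines on the processed UCI heart-disease schema (Cleveland /
Hungarian / Switzerland / Long Beach VA dialect: comma-separated, `?` for
missing, severity target `num` ∈ 0–4).

## What it computes

**QRS detection (Pan–Tompkins).**  The raw ECG x(n) passes a cascaded
band-pass, derivative, squaring and moving-window integration chain:

- low-pass `y(n) = 2y(n−1) − y(n−2) + x(n) − 2x(n−6) + x(n−12)` (DC gain 36),
- high-pass `y(n) = y(n−1) − x(n)/32 + x(n−16) − x(n−17) + x(n−32)/32`,
- derivative `y(n) = ⅛[2x(n) + x(n−1) − x(n−3) − 2x(n−4)]`,
- squaring, then a causal 150 ms moving average (53 samples at 350 Hz).

R-peak candidates are local maxima of the integrated signal above an
adaptive threshold `T = N + 0.25(S − N)` with a 200 ms refractory period,
refined back to the raw-signal maximum in a group-delay-compensated window.

**ST-segment slope.**  The ST segment — nominally 120 ms starting 20
samples after the R-peak at 350 Hz, i.e. 42 samples — has slope

    tan θ = (X − Y) / N

with `X` the last sample, `Y` the first and `N` the segment length.  The
per-recording slope (mean over beats) maps onto the ordinal `slope`
attribute (1 upsloping / 2 flat / 3 downsloping).  `oldpeak` is completed
by support-vector regression and `restecg` by a support-vector classifier
over correlation-selected predictors; `thalach` is the maximum of 20
consecutive pulse readings.

**Risk-zone classification.**  Severity `num` maps to zones (three-level:
0 green, 1 yellow, 2–4 red; two-level: 0 green, 1–4 red).  The recipe is
MICE imputation → robust scaling ((x − median)/IQR) → 0..K−1 categorical
encoding → random oversampling to class balance → 70/30 split.  A stacking
ensemble — out-of-fold base-learner probability vectors feeding a logistic
regression meta-classifier — does the classification; default base-learner
sets are {KNN, XGBoost, MLP} (two-zone) and {SVM, KNN, XGBoost}
(three-zone), and an exhaustive search over all 16 size-3/4/5 subsets of
five candidates is provided.  Evaluation reports the confusion matrix,
accuracy, macro precision/recall/F1 and per-class one-vs-rest ROC-AUC.

## Worked example

```python
from cardiorisk import (simulate_ecg, detect_r_peaks, extract_st_segments,
                        compute_st_slope, summarize_slopes, categorize_slope)

fx = simulate_ecg(fs=350, duration=30, hr_bpm=72, st_slope=0.003,
                  noise_sd=0.02, seed=42)
peaks = detect_r_peaks(fx.signal)
segs = extract_st_segments(fx.signal, peaks)
sl = summarize_slopes([compute_st_slope(s) for s in segs])
print("beats detected:", len(peaks))          # beats detected: 36
print("mean ST slope:", round(sl.summary, 5)) # mean ST slope: 0.00316
print("slope category:", categorize_slope(sl.summary))  # 1 (upsloping)
```

All 36 simulated beats are found and the measured mean slope (0.00316
amplitude-units/sample) recovers the injected 0.003 ramp; being above the
+0.002 flat band it is categorized as upsloping.  The classifier side uses
the fitted-model idiom:

```python
from cardiorisk import (simulate_cohort, RunConfig, preprocess_table,
                        StackingSpec, build_stacking)

cohort = simulate_cohort(n=600, class_proportions=(0.45, 0.28, 0.27),
                         effect_size=2.0, missing_rate=0.1, seed=42)
cfg = RunConfig(scheme="three", seed=42, split_first=True)
train, test, _ = preprocess_table(cohort.table, cfg)
results = build_stacking(StackingSpec.default("three"), train, seed=42)
print(results.evaluate_table(test).summary())
```

```
n = 180    accuracy = 0.9500
macro precision = 0.9496  recall = 0.9435  F1 = 0.9462
class      precision  recall     F1
0          0.9518     0.9875     0.9693
1          0.9388     0.8846     0.9109
2          0.9583     0.9583     0.9583
```

On this 2-pooled-SD synthetic cohort the default three-zone stack reaches
95 % held-out accuracy; class 1 (yellow, the intermediate zone) is the
hardest, as expected.  A `cardiorisk` console script exposes the same
stages (`simulate-ecg`, `simulate-cohort`, `ecg-features`, `preprocess`,
`train`, `evaluate`, `predict`).

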