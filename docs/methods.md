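# Methods

## Problem and data model

After catheter ablation for atrial fibrillation (AF), roughly half of the
patients experience a recurrence (an AF episode longer than 2 minutes after
the 3-month post-procedural blanking period). An implantable cardiac monitor
(ICM) observing a patient before ablation stores, for the last detected AF
episode, the R-R intervals of the beats preceding the onset (the
*Flashback*, ~483 beats) and of the first ~2 minutes of the episode itself
(~477 beats). The package predicts the binary recurrence outcome from heart
rate variability (HRV) features of those two series plus four clinical
covariates (age, paroxysmal vs non-paroxysmal AF, hypertension, ablation
with extra lesions beyond pulmonary-vein isolation).

A patient record is two positive, finite R-R series (Flashback >= 301
beats so all areas of interest are definable; AF episode >= 100 beats),
the covariates and the label. Cohorts serialize to two plain CSV files
(long-format R-R table plus a clinical table); interval values round-trip
bit-identically (`float_precision="round_trip"` on read). The device
quantization grid (1/256 s) can be emulated by the generator but is not
enforced by I/O: stored timestamps may or may not be grid-aligned, so the
data layer stays agnostic.

## Feature extraction

Four areas of interest (AoI) are sliced from each record: **A** the whole
Flashback, **B** its first 300 beats, **C** its last 100 beats, **D** the
stored AF-episode onset. B and C are defined independently, so for
Flashbacks shorter than 400 beats they overlap; this is allowed. On each
segment the classical 14-feature HRV battery is computed:

* time domain: mean, SDNN (sample SD, n-1), RMSSD, pNN50, pNN20 (strict
  "greater than" thresholds);
* histogram geometry: triangular index TRI = n / modal-bin count and TINN,
  the base width of the least-squares triangular fit to the interval
  histogram. Bin width defaults to 1/128 s (7.8125 ms), the conventional
  HRV histogram resolution. With the apex fixed over the modal bin the fit
  separates into independent left/right flank problems, which is how it is
  implemented; a single-bin histogram degenerates to TRI = 1, TINN = bin
  width (logged);
* complexity: ApEn (Pincus convention, self-matches included) and SampEn
  (Richman-Moorman, self-matches excluded), with m = 2 and tolerance
  r = 0.2 * SDNN of the segment — the conventional defaults, exposed in the
  config. A zero-variance segment is assigned ApEn = SampEn = 0; SampEn with
  no matching template pairs is carried as missing. Both are computed from a
  shared boolean match matrix (diagonal-shifted AND of the pairwise
  |x_i - x_j| <= r comparisons), which is algebraically identical to naive
  template counting;
* Poincare plot: SD1 = SD(successive differences)/sqrt(2),
  SD2 = sqrt(2 SDNN^2 - SD1^2) (floored at 0), and their ratio (missing when
  SD2 = 0);
* detrended fluctuation analysis (first order): integrate the mean-centred
  series, non-overlapping boxes, per-box linear detrend, F(n) = RMS
  residual; alpha1 over box sizes 4-16 and alpha2 over 16-64 (conventional
  ranges, configurable). Box sizes with fewer than two boxes are dropped;
  an exponent with fewer than two usable sizes is missing.

The **Delta** group is the within-Flashback pre-onset change,
`100 * (B - C) / B` per feature, excluding pNN50 and pNN20 whose B value is
0 for some patients (the relative change is then undefined); any feature
with B = 0 is carried as missing and flagged. The final vector per patient
is 14 (FB, from A) + 14 (L100, from C) + 12 (Delta) + 14 (AF, from D) + 4
clinical = 58 named features in a fixed order. Whether AoI A should be all
stored beats or a fixed 500-beat window is ambiguous in the protocol; A is
defined as all stored beats, with an optional `flashback_cap`.

Missing values are carried as NaN; imputation (training-set median) happens
inside the classification stage so that no statistic ever leaks from
validation or test rows.

## Classifiers, feature selection, ensembles

Five base learners (scikit-learn): SVM with linear, polynomial (degree 3)
and Gaussian kernels (C = 1, `gamma="scale"` which is ~1/n_features after
standardization), CART (Gini, no depth limit, min leaf 1, seeded) and KNN
(k = 5, Euclidean). Hyperparameters were not prescribed by the protocol;
these are the library defaults of the field and sit in the config. Features
are z-scored for the margin/distance learners (SVM, KNN) using training-row
statistics only; CART consumes raw features. Whether the original analysis
standardized at all is unknown; this choice is flagged as an assumption.

Feature selection is sequential forward floating selection (SFFS): forward
inclusion of the accuracy-maximizing feature followed by conditional
backward exclusions accepted only while they strictly improve the best
recorded accuracy at the smaller subset size. The per-size record table is
seeded with the plain greedy-forward path (sharing the evaluation cache),
so the reported best-accuracy-per-size curve dominates plain sequential
forward selection by construction and the floating step can only help. Ties
resolve to the lowest feature index, and the chosen subset is the overall
accuracy argmax with ties going to the smaller size. The selection objective
is the mean validation accuracy over a configurable number of bootstrap
train/validation splits (default 10); selection runs once per method on this
aggregated objective rather than once per repetition — the cheaper and more
stable of the two readings of the protocol, with the repetition count
exposed in the config. Each of the eight methods (five single classifiers,
three ensembles) selects its own subset, the ensembles using their own
ensemble validation accuracy as the objective.

The ensembles combine the five binary votes V(x) with a weight vector W on
the unit simplex: C(x) = 1 iff W.V(x) > 0.5, with the boundary score 0.5
mapping to class 0. Mean voting (MV) uses equal weights 0.2 (equivalent to
3-of-5 majority); accuracy-weighted voting (AWV) normalizes the single
classifiers' validation accuracies; optimum-weighted voting (OWV)
exhaustively searches the step-0.1 simplex grid — 1001 vectors, enumerated
as integer compositions of 10 into 5 parts to avoid floating-point
accumulation — for the validation-accuracy maximum, ties resolving to the
first vector in lexicographic enumeration order. OWV weights are refit per
bootstrap repetition by default (configurable to a single fit). The
ensemble ROC score is the continuous W.V(x) in [0, 1], the natural score
induced by the rule.

## Evaluation protocol

A stratified test set (8 recurrence + 8 no-recurrence by default, 22% of a
74-patient cohort) is drawn once and held fixed across repetitions. Per
bootstrap repetition the remaining patients split per class into 2/3
training and 1/3 validation (validation = round(n_class/3)); for the
74-patient cohort this gives 39 training (23 R + 16 NR) and 19 validation
(11 R + 8 NR) patients. The default is 100 repetitions. Accuracy,
sensitivity and specificity (recurrence = positive class) are averaged as
mean +/- SD over repetitions; the F1-score is computed from the
element-wise averaged confusion matrix; ROC curves and AUC come from the
pooled per-repetition test scores (a per-repetition mean AUC is also
reported). Feature-group usage per method is the percentage of its chosen
subset falling in each of FB / L100 / Delta / AF / clinical.

No-leakage is structural: selection objectives, imputation,
standardization and weight fitting only ever index train/validation rows;
a test asserts that perturbing test-row features changes neither the
selection traces nor the fitted weights.

The group-comparison table mirrors standard clinical reporting: continuous
features pass a Shapiro-Wilk gate (alpha = 0.05) per class and are compared
with the unpaired t-test (summarized mean +/- SD) when both classes look
normal, otherwise Mann-Whitney U (median, IQR); binary features use the
Pearson chi-square test without continuity correction. P-values are
reported raw (no multiplicity adjustment), matching the convention of small
pilot analyses; an adjustment can be layered on the returned table.

## Synthetic cohort generator

The clinical dataset is restricted, so the generator emulates its
statistical structure. Sinus-rhythm Flashbacks are a stationary AR(1)
(marginal SD `sinus_sd` = 35 ms, lag-1 coefficient 0.8) around a mean R-R
of 800 ms plus a sinusoidal respiratory modulation (20 ms amplitude,
period 4.5 beats), which yields realistic SDNN/RMSSD magnitudes, positive
short-range autocorrelation and DFA alpha1 near 1. The last 100 beats are
scaled by a per-class `pre_onset_delta_effect` (default 1.0 for
no-recurrence, 0.6 for recurrence), so Delta features separate classes by
construction; RMSSD of the last segment scales by exactly that factor in
expectation. AF episodes are i.i.d. Gaussian R-R jitter (per-class SD 110
vs 130 ms) around 600 ms — irregularly irregular: near-zero lag-1
autocorrelation and sample entropy far above the sinus generator's.
Clinical covariates are drawn per class with the target cohort's observed
prevalences (non-paroxysmal 18.8% vs 31.0%, hypertension 59.4% vs 61.9%,
extra lesions 15.6% vs 23.8%; age 55.5 +/- 12.8 vs 59.1 +/- 11.6 years),
and cohort composition defaults to 74 patients at 57% recurrence
(42 R / 32 NR). Beat counts are drawn at 483 +/- 33 (Flashback, floored at
301) and 477 +/- 71 (AF, floored at 100).

Two forms of heterogeneity keep the task realistically hard: each patient's
variability scales (sinus, respiratory, AF) carry a log-normal
between-patient multiplier (CV 0.3) and the mean rates Gaussian jitter
(60 / 40 ms); and the pre-onset effect itself carries per-patient
log-normal jitter (sigma 0.25) in *both* classes — every Flashback precedes
a genuine AF onset, so pre-onset autonomic change is not exclusive to
recurrence patients. Without these, a single Delta feature separates the
classes perfectly and every classifier saturates at accuracy 1.0, which no
real cohort resembles. The log-normal multipliers use mean -sigma^2/2 so
the expected scale is 1.

What the generator does **not** model: true AF electrophysiology, ectopic
beats and detection artefacts, non-stationary drift within the Flashback,
any correlation between clinical covariates and HRV magnitudes, or
frequency-domain structure beyond a single respiratory line. Passing tests
therefore demonstrate that the pipeline recovers class structure of the
kind it assumes, not that the clinical effect sizes are reproduced.

`strong_effect_config()` (pre-onset effect 0.5 for recurrence, AF
irregularity 100 vs 150 ms, extra-lesion prevalence 0.10 vs 0.40) defines
the strong-signal conditions used by the end-to-end recovery tests;
`null_effect_config()` removes all class effects.

## Numerical and design choices

* Histogram bins anchor at `floor(min/bin_width) * bin_width`, so TINN feet
  live on a deterministic edge grid.
* The SFFS iteration guard (50 forward steps per target size) is a safety
  net; backward steps require strict improvement (1e-12 margin), which
  already prevents cycling.
* Degenerate metrics (0/0) are reported as NaN and logged, never silently
  zeroed; degenerate SD2 flags the ratio as missing.
* Determinism: every stochastic step (generator, splits, CART tie-breaks)
  is seeded; identical configs give bit-identical cohorts and identical
  reports.
* Problem sizes in the shipped tests and the acceptance script are reduced
  relative to the full default protocol (25-50 bootstrap repetitions
  instead of 100, SFFS capped at 5-10 features instead of 20, 2-5
  selection splits instead of 10) — the package's own choice of desk-scale
  defaults for reproducible runs; the full protocol is a config away.

## Known limitations

* The OWV grid search and the ensembles' subset selection both maximize
  accuracy on ~19 validation patients; with moderate class effects they can
  overfit, and OWV does not dominate the single classifiers on the test set
  in every run — test metrics on 16 patients carry wide sampling bands, and
  run-to-run spread of a few accuracy points is normal at this cohort size.
* SampEn of short, highly regular segments can be undefined (no template
  matches); it is then imputed like any other missing feature.
* The chi-square test is asymptotic; with 74 patients and low-prevalence
  binary covariates its type-I rate is only approximately nominal (the
  calibration test bounds the overall false-positive rate of the mixed
  battery, not each test individually).
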