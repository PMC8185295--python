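# afrecur

Predicting atrial fibrillation (AF) recurrence after catheter ablation from
heart rate variability (HRV) features of implantable-cardiac-monitor (ICM)
R-R interval records and four clinical covariates.

## The problem

Single-procedure catheter ablation fails in roughly half of AF patients, so
triaging candidates by their probability of long-term success matters. An
ICM continuously classifies the rhythm and stores, for the last detected AF
episode before ablation, the R-R intervals of the beats preceding the onset
(the *Flashback*, ~483 beats) and of the first ~2 minutes of the episode
(~477 beats). `afrecur` turns those two series plus age, AF type,
hypertension and ablation extent (pulmonary-vein isolation only vs extra
lesions) into a prediction of recurrence — an AF episode longer than 2
minutes after the 3-month blanking period.

## The method

1. **Features.** Four areas of interest: the whole Flashback (A), its first
   300 beats (B), its last 100 beats (C), and the AF-episode onset (D). On
   each, the classical 14-feature HRV battery (mean, SDNN, RMSSD, pNN50,
   pNN20, TINN, TRI, ApEn, SampEn, SD1, SD2, SD1/SD2, DFA alpha1/alpha2).
   The *Delta* group captures the pre-onset change within the Flashback,
   `Delta(f) = 100 * (f(B) - f(C)) / f(B)`, excluding pNN50/pNN20. Together
   with the clinical covariates: 58 named features per patient.
2. **Classifiers.** Five base learners — SVM with linear, polynomial and
   Gaussian kernels, CART, and KNN — each with training-median imputation
   and (for the margin/distance learners) z-scoring baked in. Sequential
   forward floating selection (SFFS) picks one feature subset per method by
   maximizing validation accuracy.
3. **Ensembles.** The five binary votes `V(x)` are combined with a weight
   vector `W` on the unit simplex: `C(x) = 1 iff W.V(x) > 0.5`. Mean voting
   (`W_i = 0.2`, i.e. 3-of-5 majority), accuracy-weighted voting
   (`W_i = acc_i / sum(acc)`), and optimum-weighted voting (exhaustive
   search over the 1001-point step-0.1 simplex grid for the
   validation-accuracy maximum).
4. **Evaluation.** A stratified 8+8 test set (22% of a 74-patient cohort)
   is fixed once; the rest is re-split 2/3 train / 1/3 validation per
   bootstrap repetition (default 100). Accuracy, sensitivity and
   specificity are averaged over repetitions, the F1-score comes from the
   averaged confusion matrix, and ROC/AUC from pooled test scores.

The real clinical dataset is restricted, so the package ships a synthetic
cohort generator (`afrecur.synthetic`) that emulates its structure: AR(1)
sinus rhythm with respiratory modulation, a class-dependent pre-onset
variability change in the last 100 Flashback beats, irregularly-irregular
AF series, per-class clinical prevalences, and realistic between-patient
heterogeneity. See `docs/methods.md` for the model, every tunable and the
generator's limitations.

## Worked example

```python
import afrecur as af

cohort = af.simulate_cohort(af.SyntheticConfig(seed=1))   # 74 patients, 42 recurrence
config = af.AnalysisConfig(n_repetitions=25, sffs_max_size=10,
                           n_selection_repetitions=5, seed=2)
report = af.run_experiment(cohort=cohort, config=config)
print(report.format_summary())
```

prints (a ~2-minute run):

```
Test-set performance (mean +/- SD over repetitions):

  svm_linear   accuracy 0.75 +/- 0.00  sensitivity 0.88  specificity 0.62  F1 0.78  AUC 0.84
  svm_poly     accuracy 0.75 +/- 0.05  sensitivity 0.94  specificity 0.56  F1 0.79  AUC 0.86
  svm_gaussian accuracy 0.59 +/- 0.05  sensitivity 0.82  specificity 0.36  F1 0.67  AUC 0.65
  cart         accuracy 0.66 +/- 0.08  sensitivity 0.72  specificity 0.60  F1 0.68  AUC 0.66
  knn          accuracy 0.70 +/- 0.06  sensitivity 0.86  specificity 0.55  F1 0.74  AUC 0.78
  mv           accuracy 0.64 +/- 0.02  sensitivity 0.77  specificity 0.50  F1 0.68  AUC 0.68
  awv          accuracy 0.64 +/- 0.02  sensitivity 0.77  specificity 0.50  F1 0.68  AUC 0.68
  owv          accuracy 0.53 +/- 0.07  sensitivity 0.77  specificity 0.29  F1 0.62  AUC 0.54

Selected features:
  svm_linear   (3): l100_pnn20, delta_sdnn, af_type
  svm_poly     (6): fb_sd1sd2_ratio, l100_dfa_alpha1, delta_rmssd, delta_sdnn, af_pnn50, hypertension
  ...
```

Reading it: each row is one classification method; accuracy, sensitivity
(recurrence detection) and specificity are means over the 25 bootstrap
repetitions on the held-out 16-patient test set, F1 comes from the averaged
confusion matrix, AUC from the pooled test scores. The selected-feature
lists show what SFFS chose per method — here mostly Delta and last-100-beat
features, which is where the generator injects the class effect. On a
16-patient test set these metrics carry wide sampling bands, and the
optimum-weighted ensemble can overfit its validation-set weight search on
moderate-signal cohorts (as on this seed); `report.per_repetition`,
`report.group_usage` and `report.weights` hold the full detail, and
`af.plot_report(report, "figs/")` renders the accuracy-vs-subset-size and
ROC figures.

The same pipeline is scriptable from the shell:

```sh
afrecur simulate --seed 1 --out cohort/
afrecur extract  --cohort cohort/ --out features.csv
afrecur evaluate --features features.csv --out report/
afrecur report   --report report/
```

Estimator-style classes (`SingleClassifier`, `SFFSSelector`,
`VotingEnsembleClassifier`, `HRVFeatureExtractor`) expose the same pieces
with scikit-learn `fit`/`predict`/`transform` conventions for standalone
use.

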