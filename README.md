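# trunkrun

Risk modeling of lower-limb overuse injuries (LLOI) from a single
trunk-mounted tri-axial accelerometer worn during a 12-minute Cooper run.

Overuse injuries develop gradually when musculoskeletal load outpaces
capacity, and they account for the bulk of running-related injuries.
`trunkrun` is for sports scientists and biostatisticians who want to turn
one field test per athlete — a lower-back accelerometer recording plus a
short questionnaire (mass, height, gender, previous injuries, insoles,
distance covered) — into a cross-validated injury-risk classifier and an
interpretable account of which feature categories drive the prediction.
Because cohort accelerometry of this kind is rarely public, the package
ships a synthetic-cohort generator with known ground truth so the entire
pipeline is testable and demonstrable end to end.

## What it computes

**Preprocessing.** Sensor tilt is estimated from mean horizontal
accelerations (θ = arcsin(ā), with ā in g), removed by sequential plane
rotations, and 1 g of static gravity subtracted. Running stages are located
from vertical-acceleration peaks (running ≈ 2.6–3.2 steps/s with >2 g
impacts; walking is slower and softer), the unsteady first minute and last
ten seconds of every stage are cropped, and the remainder is re-corrected
in non-overlapping two-minute windows so a fatigue-driven change of trunk
lean cannot corrupt the whole-series correction. Subjects are excluded if
they had a non-overuse injury, unknown follow-up status, missing values, or
under ten minutes of detected running.

**Features.** On 10-second subwindows: step/stride regularity
(autocorrelation at the step and stride lag), RMS ratios, sample entropy
SampEn(m=2, r=0.2·SD), post-contact impact magnitude, and a generic
statistical bank (moments, ranges, change and spectral statistics) per axis
(VT/ML/AP) and for the resultant. Values are min-max normalized per subject
against the first six subwindows — so later windows express within-run
change — and averaged; trunk-lean angle change (last minus first two-minute
window) and step time pass through unnormalized.

**Risk model.** Inside every cross-validation fold: one-hot encoding +
standardization → PCA → ANOVA-F selection of components → a class-weighted
classifier (L1 logistic regression, random forest, or SVM with cross-fitted
Platt scaling). Hyperparameters (number of PCA components, number of
selected components, classifier knobs) are tuned by grid search on a 3-fold
inner CV maximizing AUC; outer folds (5, or 6 for female-specific cohorts)
estimate generalization AUC and Brier score.

**Importance.** For logistic models, the sensitivity of the injury log-odds
to feature *f* is propagated through the PCA loadings:

    importance_f = | Σ_i  w_i · PC_if |

and summarized per feature category (direction, type, or both) as the
category mean normalized to a proportion across categories.

## Worked example

```python
import numpy as np
from trunkrun import SignalParams, CohortParams, simulate_cohort, GaitFeatureExtractor
from trunkrun.features import attach_questionnaire, remove_constant_features
from trunkrun.modeling import nested_cv_evaluate

sp = SignalParams(duration_s=720, fs=100)           # 12-minute trials
cp = CohortParams(n_subjects=200, prevalence_target=0.25,
                  effect_sizes={"drift": 2.5}, seed=42)
sim = simulate_cohort(sp, cp)

extractor = GaitFeatureExtractor().fit()
table = attach_questionnaire(extractor.transform(sim.traces), sim.records)
table, _ = remove_constant_features(table)

keep = ~table.values.isna().any(axis=1)             # exclusion criterion 3
y = np.array([int(r.status == "LLOI") for r in sim.records])[keep.to_numpy()]
res = nested_cv_evaluate(table.subset("All").values[keep], y, algorithm="LR", seed=1)
print(f"mean AUC {res.mean_auc:.3f} +/- {res.sd_auc:.3f}, "
      f"mean Brier {res.mean_brier:.3f}")
```

Output:

```
mean AUC 0.906 +/- 0.056, mean Brier 0.145
```

The cohort carries a known injected effect — 2.5 log-odds per SD of the
trunk-lean drift latent, a fatigue signature — so a mean outer AUC around
0.9 means the nested-CV pipeline recovered most of the Bayes-attainable
discrimination (~0.90 for this effect size); chance would be 0.5.

A command-line workflow covers the same ground stage by stage:

```bash
trunkrun simulate --n 50 --seed 1 --out data/
trunkrun preprocess --traces data/traces --cohort data/cohort.csv --out pre/
trunkrun extract --traces data/traces --cohort pre/cohort_included.csv --out features.csv
trunkrun train-eval --features features.csv --cohort pre/cohort_included.csv \
    --cohort-split all --subset All --algo LR --seed 1 --out model/
trunkrun importance --features features.csv --cohort pre/cohort_included.csv \
    --scheme direction --out importance/
```

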