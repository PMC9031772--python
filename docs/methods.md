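# Methods

This note documents the models, procedures and numerical choices behind
`trunkrun`, in the package's own terms: what is computed, under which
assumptions, which knobs matter, and what the synthetic experiments do and
do not demonstrate.

## Signal model of a simulated Cooper test

A recording is built in a level "world" frame and then rotated into the
tilted sensor frame.

* **Steps.** Foot contacts occur at the subject's cadence (default
  2.8 steps/s). Each contact adds a damped half-sine transient of ~50 ms to
  the vertical axis, with fixed leakage of 20% into the anterior–posterior
  (AP) axis and 10% into the medial–lateral (ML) axis; the ML leakage
  alternates sign with the stance foot. Left and right amplitudes are
  `impact·(1 ± asymmetry)`. Every transient is balanced by a shallow
  negative offset spread over its step interval so the dynamic component
  integrates to zero per step — over a stride the runner returns to the
  same vertical velocity, and this zero-mean property is precisely what the
  arcsine tilt estimator assumes.
* **Gravity and tilt.** A constant 1 g field is rotated by the sensor tilt
  (AP and ML angles). The rotation applied is the exact inverse of the
  correction rotation, so correcting with the true angles recovers the
  level frame to machine precision.
* **Fatigue.** Fatigue appears as a linear drift of the AP lean angle over
  the trial (`drift_deg`) coupled to a linear ramp of the white-noise SD
  (0.15 relative increase per degree of lean drift, overridable via
  `noise_ramp`). Both signatures are recoverable downstream: the drift
  through the unnormalized lean-angle-change feature, the ramp through the
  per-subject-normalized variability features.
* **Walking breaks** halve the cadence and scale impacts to 35% —
  below the running-detection threshold by construction.
* Samples are clipped to ±16 g, the sensor's measuring range. Defaults are
  a 720-s trial at 1000 Hz.

### Cohort model

Per-subject latent gait parameters are drawn from truncated normals:
cadence 2.9±0.15 steps/s, impact 3.0±0.5 g, asymmetry 0.12±0.06,
lean drift 2.0±1.5°, noise SD 0.15±0.04 g. The injury label is Bernoulli
with log-odds `intercept + Σ β_l·z_l` over cohort-standardized latents
(`z`), plus optional female-interaction terms; the intercept is solved with
Brent's method so the mean probability equals the target prevalence
(default 0.25, the study-like rate). Questionnaire fields come from
gender-conditional normals (male 71.38±7.56 kg, 179.86±6.33 cm; female
62.51±6.63 kg, 167.19±5.99 cm; Cooper distance 3000±200 m male,
2600±200 m female; previous-injury rate 0.3; insole rate 0.15). A
ground-truth sidecar (latents, linear predictor, probability, label) is
returned for recovery tests.

**What the generator does not emulate:** real gait dynamics (joint
kinematics, stride-to-stride autocorrelation structure, surface and shoe
effects), GPS/track geometry, heteroscedastic sensor noise, or any true
physiological injury mechanism. Passing tests therefore show that the
pipeline recovers the kinds of between-subject signal it is built to
detect (fatigue drift, cadence, asymmetry, impact level) at realistic
noise levels — not that it would achieve comparable discrimination on real
cohorts, where the injury–gait link is far weaker and confounded.

## Preprocessing

1. **Tilt estimate** over a segment: θ_AP = arcsin(mean AP), θ_ML =
   arcsin(mean ML), accelerations in g. Valid while mean dynamic
   acceleration ≈ 0 and |mean| < 1 g (violations raise).
2. **Correction**: rotation in the AP–VT plane by θ_AP, then in the ML–VT
   plane by θ_ML, then subtraction of 1 g from the vertical axis. The
   rotation is an isometry; tests check norm preservation to 1e-12.
3. **Stage detection** on the whole-series-corrected vertical signal, in
   5-s blocks: a block is running iff at least `c_min`·5 peaks (min
   spacing 0.25 s, prominence ≥ τ/2) rise ≥ τ above the block median and
   the median peak height is ≥ τ. Defaults τ = 1.4 g, c_min = 2.2 steps/s —
   running (≈2.6–3.2 Hz, ~3 g peaks) and walking (≈1.4 Hz, ~1 g peaks)
   sit on opposite sides with a wide margin. All thresholds are
   configurable; no canonical values exist.
4. **Cropping**: first 60 s and last 10 s of every stage removed
   (start-of-test jostling, end-of-test sprints/decelerations). Stages
   shorter than 70 s vanish.
5. **Windowed correction**: each cropped stage is re-corrected in
   consecutive 120-s windows (tail remainder discarded), with the window's
   own tilt estimate taken on the raw signal. This bounds the
   constant-tilt violation under fatigue drift; with 6° of drift the
   per-window corrected means stay within ~1e-3 g of zero.
6. **Start-of-test trimming** is not automated: recordings are assumed
   pre-trimmed to the test, and `flag_leading_quiet_segment` flags a
   leading ≥5-s low-variance stretch for manual inspection instead. The
   quiet standing period before a mass start is obvious to a human and
   error-prone to cut blindly.

**Exclusion filter** (first matching criterion wins): non-overuse injury;
unknown follow-up status; any missing questionnaire or feature value; less
than 600 s of detected running. Running time is counted pre-cropping — the
requirement concerns how much of the test was actually run, not how much
survives cropping.

## Features

Features are computed on 10-s subwindows of the corrected 2-min windows;
the window grain balances stationarity against estimator variance, and six
subwindows (one minute) define each subject's normalization reference.

* **Step detection**: vertical-acceleration maxima, prominence ≥ 1 g,
  spacing ≥ 0.25 s. Under 4 events marks the subwindow unusable for
  step-based features.
* **Regularity**: unbiased normalized autocorrelation; the step lag is the
  first autocorrelation peak past 0.2 s, the stride lag twice that. Values
  clipped to [−1, 1] (the unbiased estimator can slightly exceed 1).
* **Sample entropy**: SampEn(m=2, r=0.2·SD), Chebyshev distance, matches
  counted with d ≤ r, self-matches excluded. The signal is resampled to
  100 Hz first: above that rate the O(N²) count is intractable and the
  statistic is dominated by sample-to-sample noise correlation. A numba
  kernel does the counting, with a pure-numpy fallback.
* **Impact**: mean over steps of the peak |acceleration| within 100 ms of
  contact.
* **Lean angles**: the per-window tilt estimate on the raw signal *is* the
  trunk-lean angle; the feature is last-window minus first-window angle per
  horizontal axis (needs ≥ 2 windows, otherwise missing). Centered, never
  min-max normalized.
* **Statistical bank** (per axis and resultant): mean, SD, RMS, min, max,
  range, median, IQR, skewness, kurtosis, mean absolute change,
  zero-crossing rate (after mean removal), prominent-peak count, dominant
  frequency, spectral power fractions in [0,3), [3,10), [10,30) Hz,
  spectral entropy, lag-one-sample autocorrelation, line length. Spectral
  quantities exclude DC; moment features undefined on constants come back
  missing.
* **Normalization**: per subject and feature, min/max over the first six
  subwindows; reference windows map into [0,1] exactly, later windows may
  exceed it (that is the point — they encode within-run change).
  Degenerate (constant) references map to 0.
* **Aggregation**: mean over subwindows (missing ignored); SD over
  subwindows added for sample entropy and impact. Step time is computed
  once per subject from the pooled step intervals and passes through
  unnormalized, as do the angle changes and the questionnaire features
  (distance, gender, mass, height, previous injury, insoles).
* Features constant across all subjects are removed (e.g. the resultant's
  RMS ratio, identically 1).

Missing values propagate as missing and feed exclusion criterion 3 rather
than being imputed; imputation would blur the cohort definition.

## Risk modeling

All fold-local: one-hot encoding of categoricals and standardization of
numerics (training statistics only) → PCA (`n_pca` components) → selection
of the `k_select` components with the largest ANOVA F-statistic against
the label → classifier with class weights inversely proportional to the
training class frequencies. Classifiers: L1 logistic regression
(liblinear or saga solver; C grid {0.01, 0.1, 1, 10}), random forest
(100 trees, depth 3–4, min split 3–4, gini/entropy, min impurity decrease
{0, 0.01}), SVM (poly degree 1–3 / rbf / sigmoid; probabilities via Platt
sigmoid cross-fitted 3-fold within the training split — refitting the
sigmoid on the training scores would be optimistically calibrated).
`n_pca` ∈ {10, 15, 20, 25, 30}, `k_select` ∈ {2..6}.

Nested CV: stratified outer folds (5; 6 for female-specific cohorts, whose
grid omits 30 components because the cohort is small), 3-fold inner grid
search maximizing mean AUC, winner refit on the full training split,
scored on the held-aside test split (AUC and Brier). Stratification is a
deliberate choice so small cohorts keep both classes in every fold. Grid
ties break deterministically toward smaller `n_pca`, then smaller
`k_select`, then lexicographic parameters — the simplest model wins a tie.
Gender-specific cohorts drop the (now constant) gender column. Pooled ROC
curves concatenate the outer-fold test predictions, each subject appearing
exactly once.

A property worth stating explicitly: PCA is unsupervised, so label signal
concentrated in a *single* standardized feature among ~100 is largely lost
in the top ≤30 components — recovery requires the signal to span a
correlated block of features (as fatigue does) or a small feature subset.
This is a real limitation of the modeling design, visible in the
experiments, not an implementation artifact.

## Importance

For a fitted logistic model, `importance_f = |Σ_i w_i·PC_if|` composes the
model coefficients over its selected components with the PCA loadings —
the absolute sensitivity of the injury log-odds to standardized feature
*f*, holding other features fixed. It lives in the post-encoding
standardized space (one-hot levels reported separately); unselected
components contribute nothing; cancellation between components is
intentional (only the size of the net influence matters). Category
summaries divide each category's mean member importance by the total of
the category means, yielding proportions that sum to one; the mean (not
sum) compensates for unequal category sizes. Three schemes: direction
(VT/ML/AP/resultant/non-directional), type
(sports-specific/statistical/questionnaire), and their combination.
Importances are reported per outer fold and fold-averaged; both a
full-cohort refit and fold averaging are defensible, and both are exposed.

## Reference experiments and problem sizes

The canned experiments (`trunkrun.experiments`) use 200 subjects with
12-minute trials synthesized at 100 Hz — every gait feature of interest
lives far below 50 Hz, and the lower rate keeps the full cohort tractable
on one CPU (the resampling step before sample entropy also becomes the
identity). The reference injected effect is 2.5 log-odds per SD of the
lean-drift latent: a 2×10⁶-sample simulation of the Bayes-optimal score
puts the attainable AUC ceiling for that effect near 0.90 at 25%
prevalence, so the pipeline's measured ~0.83–0.91 means most of the
available discrimination is recovered. The permuted-label baseline uses a
reduced grid (a null AUC does not depend on tuning finesse); the leakage
sentinel replaces one feature with the label in test folds only and checks
no fold reaches a perfect AUC.

## Known limitations

* The synthetic data's injury mechanism is, by construction, exactly the
  kind of signal the features measure; real effect sizes are far smaller.
* Subject-level min–max normalization deliberately discards most
  between-subject level information in the windowed features; absolute
  levels survive only through step time, the angle changes and the
  questionnaire. Models built on these features are fatigue-change
  detectors more than absolute-gait classifiers.
* Tilt correction assumes a quasi-static 1 g field per window; violent
  non-stationarities within a window (e.g. a fall) bias the window's
  angles.
* SampEn is missing for (near-)constant windows and for windows without
  template matches; short windows make it noisy.
* The importance statistic treats features as independently perturbable;
  correlated features (an axis and the resultant) share credit in ways
  that should be read qualitatively.
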