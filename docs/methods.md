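# Methods

## Problem and pipeline

`pedmet` predicts whether a child with overweight or obesity will be
diagnosed with type 2 diabetes (T2D), metabolic syndrome, or prediabetes
before age 18, from longitudinal EHR-style data available in an earlier
*observation window*.  The pipeline has seven stages:

1. **EHR tables** (`pedmet.io`): six delimited text tables keyed by patient,
   with all events timestamped in fractional years of age.
2. **Anthropometry** (`pedmet.growth`): BMI, LMS z-scores/percentiles against
   a growth reference, CDC-style weight classes.
3. **Phenotyping** (`pedmet.phenotype`): rule-based case/control labels plus
   the inclusion and activity filters.
4. **Trajectories** (`pedmet.trajectories`): per-year BMI and visit-count
   vectors, truncation at onset, z-score normalization.
5. **Cohort assembly and feature selection** (`pedmet.cohorts`).
6. **Models and evaluation** (`pedmet.models`, `pedmet.evaluation`).
7. **Explanations** (`pedmet.interpret`).

A synthetic-data module (`pedmet.simulate`) generates cohorts with known
ground truth so every stage is testable without patient data.

## Growth reference and anthropometry

BMI-for-age is standardized by the LMS method: with Box-Cox power L, median
M and coefficient of variation S at a given age and sex,
`z = ((X/M)^L - 1)/(L*S)` (or `ln(X/M)/S` when `L = 0`), and the percentile
is `100*Phi(z)`.  L, M, S are linearly interpolated in age within sex.
Weight classes: underweight < 5th percentile, normal [5, 85), overweight
[85, 95), obesity >= 95th, and severe obesity when BMI >= 120% of the
95th-percentile BMI.

The bundled table (`data/cdc_lms_synthetic.csv`) is **synthetic**: it has the
CDC file layout (sex, agemos, L, M, S) and realistic magnitudes (median BMI
dipping near the adiposity rebound at ~5.5 y, rising through adolescence;
L ~ -2; S ~ 0.09-0.14), but it is not the measured CDC reference.  The loader
accepts any table in the same layout, so the real CDC file drops in
unchanged.

Two numerical notes.  With L < 0 the LMS transform has a finite asymptote at
`z = -1/(L*S)`; the inverse transform clamps just inside it so extreme
z-scores map to extreme but finite BMIs.  The same geometry means the
measurement outlier rule (drop |z| > 8, applied at load time when a reference
is supplied) is one-sided in practice: impossibly *low* BMIs are caught,
while the z of a high BMI saturates near the asymptote.  The nonpositive
height/weight rule is always applied.  Both thresholds are arguments of
`read_patient_tables`.

## Outcome definitions

All code lists and thresholds live in editable YAML
(`data/outcomes.yaml`); the shipped defaults are:

* **T2D** — a composite in the spirit of multi-site EHR phenotyping
  algorithms: a type-2 ICD code AND supporting evidence (an oral
  antidiabetic medication or fasting glucose >= 126 mg/dL, HbA1c >= 6.5%, or
  random glucose >= 200 mg/dL), excluding patients whose diabetes codes are
  type-1 only.
* **Metabolic syndrome** — ICD 277.7 / E88.81, or the IDF pediatric
  composite: central adiposity (waist >= 90th percentile, proxied by BMI
  percentile >= 90 when waist is absent) plus at least two of triglycerides
  >= 150 mg/dL, HDL < 40 mg/dL, blood pressure >= 130/85 mmHg (systolic and
  diastolic count as one component), fasting glucose >= 100 mg/dL.
* **Prediabetes** — ICD 790.2x / R73.x, or fasting glucose 100-125 mg/dL, or
  HbA1c 5.7-6.4%.

A case's onset age is the earliest firing event; the IDF composite is
treated as a single event dated when its criteria complete.  Labels carry an
evidence list so any rule decision is auditable.  Mean onset ages used for
truncation and window construction: 13.4 y (T2D), 12.5 y (metabolic
syndrome), 12.3 y (prediabetes).

Inclusion requires >= 2 height/weight records from different months (ages
>= 1/12 y apart), >= 1 BMI at or above the 85th percentile, and continued
activity: no gap longer than 3 years in {12} ∪ {encounter ages in (12, 18]}
∪ {18}.  This gap construction is equivalent to "at least one visit in every
3-year subinterval after age 12" and fixes the endpoint behaviour the prose
rule leaves open.

## Trajectory harmonization

BMI trajectories are partitioned into half-open one-year segments [y, y+1);
a record at an exact integer age belongs to the segment it starts.  Each
segment's value is the mean of its BMIs; interior empty segments are filled
by linear interpolation between the nearest observed segment means (in
segment index).  No extrapolation: a window is *covering* only if some
observed segment lies at or before its first year and at or after its last
year, and non-covering patients are excluded.  One interpolation rule is
applied regardless of whether an empty year had encounters without BMI or no
contact at all.  The visit channel counts distinct encounter days per year
(day = age rounded at 1/365.25 resolution); zeros are genuine zeros and are
never interpolated.

Records at or after the cohort's mean onset age — and, for cases, at or
after their own diagnosis age — are dropped before harmonization, so no
post-onset information leaks into predictors.  Observation windows [s, e)
range over all integer pairs 2 <= s < e <= floor(mean onset age): 66 windows
for T2D, 55 each for metabolic syndrome and prediabetes.  Assembled cohorts
with fewer than 20 surviving patients are dropped.

Z-score normalization is fit per column on training rows only (population
SD, divisor n; constant columns map to 0) and travels with the model.

## Wide features and selection

Candidate scalar features are one-hot demographics (sex, race, insurance;
first level is the reference) and ever/never indicators of ICD codes
observed in the window in at least 5 patients.  Selection is two-stage:

1. univariable logistic Wald tests per feature, Benjamini-Hochberg adjusted,
   keeping q < 0.05 (constant features get q = 1; a likelihood-ratio
   fallback handles separation);
2. an L1-penalized logistic path over 30 log-spaced penalties with the
   glmnet-style one-standard-error rule on 3-fold cross-validated binomial
   deviance; features with nonzero coefficients at that penalty are kept.
   An empty selection is a valid outcome.

## Models

All classifiers end in a two-way softmax trained with categorical
cross-entropy (rather than a one-unit sigmoid), matching the stated cost
function.  The neural architectures run on a small in-package numpy
autodiff core (`pedmet.nn`), whose gradients are pinned by finite-difference
tests.

* **DW-TSF-CNN** (flagship): a deep branch combining time-series-forest
  interval features — mean, population SD and least-squares slope over
  `ceil(sqrt(T))*3` randomized intervals per channel, fixed by the seed —
  with 1-D convolutional features over the (BMI, visits) trajectory, joined
  with a purely linear *wide* branch over the selected scalar features, then
  merged into the softmax head.
* **TSF-CNN**: the deep branch only, on the BMI channel only (the
  trajectory-only comparator).
* **Most-recent-BMI logistic regression**: a single-predictor network on the
  final window year's BMI, which reduces to logistic regression.
* **Random forest**: scikit-learn, on flattened trajectory plus wide
  features.
* **CRNN**: 1-D convolution, GRU, layer normalization and dropout, wide
  features concatenated at the head.
* **Transformer**: one encoder block (multi-head self-attention and a
  feed-forward sublayer, each with residual connection, layer normalization
  and dropout), sinusoidal positions, mean-pooled, wide features at the
  head.

Training: Adam, initial learning rate 0.001, batch size 32, up to 500
epochs.  The learning rate is multiplied by 0.92 whenever the training loss
fails to improve for 3 consecutive epochs.  Early stopping halts training
after 15 epochs without improvement of the monitored loss; the monitor is an
internal stratified validation split (15% by default) when both classes
allow one, otherwise the training loss, and the best-monitor weights are
restored.  The per-epoch history (train loss, validation loss, learning
rate) is stored on the fitted model; the learning-rate sequence is
reproducible from the loss history alone.

Hyperparameter search is random sampling from a small documented space
(filters, hidden width, dropout, heads, head size, feed-forward width) with
a stratified 20% tuning split carved from the training ids only.

## Evaluation protocol

Per iteration (10 by default, seeded as base seed + iteration): a stratified
80/20 train/test split exact to the nearest patient; optional hyperparameter
search; stratified 3-fold cross-validation on the training set with the mean
CV AUC recorded; the decision threshold chosen by maximizing Youden's J
(sensitivity + specificity - 1) on the pooled out-of-fold validation scores,
ties resolved toward the higher threshold (better specificity), frozen
before the test set is touched; a final fit on the full training set; test
AUC, sensitivity and specificity at the frozen threshold.  Medians across
iterations are the headline numbers.  AUC is the Mann-Whitney statistic
(ties count 1/2).

Model comparison across windows uses the tie-corrected Friedman rank test
(blocks = windows, rank 1 = highest AUC) with the Nemenyi critical distance
at alpha = 0.05 for the critical-difference display.  The
longitudinal-versus-recent comparison pairs per-iteration test AUCs across
identical windows, reports the median percent improvement
`100*(AUC_traj - AUC_recent)/AUC_recent`, and tests significance with the
one-sided Wilcoxon signed-rank statistic; the pairwise test is chosen for
distribution-freeness since the underlying AUC differences are not modelled.

## Explanations

Shapley attributions are estimated by permutation sampling on the
probability scale (so per-patient scores read as probabilities).  Features
are the flattened trajectory positions per channel plus the wide features.
For each sampled ordering, every path point is evaluated against the full
background (at most 100 training rows), which Rao-Blackwellizes the usual
one-row pairing and makes 20 permutations sufficient for stable
attributions; telescoping guarantees that base value plus attributions equal
the prediction up to float error (tolerance 1e-3 is asserted).  The estimator
is validated against exhaustive coalition enumeration on a 3-feature model.

A trajectory channel's per-patient importance is its largest absolute
position attribution (earliest position on ties); global importance is the
mean absolute attribution pooled over patients and windows after that
reduction.  A patient's call is positive iff prediction >= threshold.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes:

* **Growth**: each child carries a latent BMI z-score process
  `z(age) = z0 + s*(age - 2) + noise`, with `z0 ~ N(0.85, 0.65)` (a cohort
  enriched for overweight), slope `s ~ N(0.015, 0.05)` per year, and
  measurement noise SD 0.15 z; z is clipped to [-3, 3.5] (inside the LMS
  support) and inverted through the growth reference; height comes from a
  median height-for-age curve with a per-child proportional deviation, and
  weight follows from BMI and height.
* **Visits**: a renewal process at `mean_visits_per_year` (default 2.0) with
  patient-level gamma rate heterogeneity controlled by
  `visit_overdispersion` (default 0.5); 5% of patients stop visiting early,
  exercising the activity filter.  A fraction `missing_year_rate` (default
  0.15) of calendar years carry no measurements.
* **Outcome**: case status is Bernoulli under a logistic link on the wide
  features (default log-odds: obesity code 0.8, weight-gain code 0.6,
  Medicaid 0.5, female 0.3, vaccination encounter -0.4), with the intercept
  solved numerically so realized prevalence matches the target (default
  0.10); cases' z-slopes then drift upward by `traj_signal_effect`
  (default 0.12 z/year).  Cases emit outcome-specific diagnoses/labs/
  medications after an onset age uniform on [9, 16] with probability 0.97;
  controls false-emit at 0.005, so phenotyping recovers the latent truth in
  >= 95% of patients but not tautologically.

The latent case indicator is available to tests via `truth_labels` and never
enters the flat files the pipeline reads.  Defaults are chosen once as the
study conditions; the visit-process parameters are placeholders exposed in
config because no distributional description of a real cohort's visit
process is assumed.

What the simulator does **not** emulate: secular trends and calendar-time
effects, code ontology depth (a handful of codes stand in for thousands),
informative missingness correlated with disease severity, medication effects
on growth, and measurement error structure beyond i.i.d. noise.  Passing
tests therefore demonstrate that the pipeline recovers signal with the
assumed structure, not clinical-grade performance on real EHR data — the
published AUCs of the real-data study are not reproducible at desk scale and
are not targets here.

## Verification problem sizes

The test suite exercises the full pipeline at sizes chosen for tight
Monte-Carlo behaviour at desk scale: signal recovery uses cohorts of 2000
simulated patients over 5 seeds (trajectory-only TSF-CNN must beat the
most-recent-BMI logistic regression by >= 0.05 median AUC); null calibration
uses 4500 patients at prevalence 0.3 over 5 seeds (every model kind's median
test AUC must land in [0.45, 0.55] — the higher prevalence shrinks the AUC's
null standard error so the band is a ~2.6-sigma check); signal monotonicity
uses 1200 patients at three effect levels.  Epoch budgets in tests (30-300
by model) are computational choices; the 500-epoch default stands for real
use.  The most-recent-BMI logistic model gets at least as many epochs as its
comparators because, having two effective parameters, it converges slowest
under the fixed Adam schedule.

## Known limitations

* The deep models are small numpy implementations; they are exact in
  gradient and schedule semantics but not performance-tuned for large
  cohorts or long windows.
* The Nemenyi table covers 2-10 models at alpha = 0.05 only.
* Onset-age prediction (when, not whether) is out of scope, as are
  calibration analysis, temporal ICD-sequence features, and
  medication-effect modelling.
* The IDF composite requires concurrent lab availability; with the sparse
  labs typical of pediatric records the ICD branch dominates in practice.
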