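# Methods

`pmtl` implements a personalized-modeling framework for binary clinical
risk estimation, built around acute kidney injury (AKI) in hospitalized
adults. This note records the models, the operational choices behind every
under-determined step, the synthetic cohort the test suite runs on, and
the limits of what those tests demonstrate.

## Cohort construction and KDIGO labeling

Time is measured in real-valued hours from admission (t = 0); all windows
are closed intervals.

**Baseline creatinine.** The last serum creatinine (SCr) measurement in
[-48 h, 0), else the first measurement at t >= 0. A stay with neither is
unlabelable and is excluded.

**AKI (KDIGO stage >= 1, creatinine criteria only).** Each in-stay
measurement at time t is AKI-positive if (a) it exceeds the minimum SCr in
its trailing 48-h window — the baseline draw included whenever its time
falls in the window — by >= 0.3 mg/dL, or (b) it reaches 1.5x the fixed
admission baseline. Onset is the earliest positive time. Choices made
here, where KDIGO operationalizations legitimately differ: the 1.5x
comparison uses the fixed admission baseline rather than a rolling 7-day
baseline (the simplest reading of the baseline rule); urine-output and
stage 2-3 criteria are out of scope; comparisons carry a 1e-9 tolerance so
exact-threshold values (e.g. 1.5 x 0.8 = 1.2) are not lost to floating
point. Onset is monotone: appending later measurements never moves an
established onset earlier.

**Eligibility.** Exclusions, counted by first matching reason, in order:
fewer than 2 SCr measurements; no computable baseline; baseline MDRD eGFR
(4-variable IDMS form: 175 x SCr^-1.154 x age^-0.203 x 0.742 if female x
1.212 if Black) below 60 mL/min/1.73 m^2; any SCr > 1.3 mg/dL within
[0, 24 h]. Stays whose estimation point would precede admission are
likewise dropped.

**Estimation point.** 24 h before AKI onset for cases, 24 h before the
last SCr measurement for non-cases. Features used by the models must be
knowable at this time; the simulator guarantees this by construction
(static features), and real-data users must enforce it upstream.

## Preprocessing

Statistics are learned on training data only. Continuous features are
median-imputed and z-scored; binary features are median-imputed and kept
0/1; every feature with any missingness in training contributes a 0/1
missing-indicator column that downstream models and the distance metric
treat as an ordinary binary feature. Constant columns get unit scale
rather than dividing by zero. Missingness handling is
median + indicator rather than anything model-based: it is transparent,
deterministic, and standard practice for EHR feature matrices.

## Models

The base learner everywhere is penalized logistic regression, fit by
L-BFGS on the analytic gradient. On the total-log-likelihood scale the
objective is

    sum_i log(1 + exp(-y~_i (a + x_i'b)))
        + lambda_a (||b - b0||^2 + (a - a0)^2)   [transfer fits only]
        + lambda_r ||b||^2,

with y~ in {-1, +1}. The ridge acts on coefficients only (intercept
unpenalized); the anchor acts on the full parameter vector, pulling toward
the initializing model (a0, b0), from which optimization also starts.
Standard errors come from the observed information of the penalized
objective (X'WX plus the penalty curvature); penalization therefore
slightly shrinks them — a documented caveat for the metaregression, which
consumes these SEs.

**Transfer strength.** Defaults are lambda_a = 20, lambda_r = 1 on the
total-likelihood scale. The scale matters: the Fisher information a
neighborhood of k patients carries per coefficient is roughly
k x p(1-p) x var(x) (about 25-80 for k = 500-1600 at ~10% prevalence), so
an anchor of this order shares weight evenly with the local data at
typical neighborhood sizes, protects strongly when k is small (the
small-sample regime transfer learning exists for), and fades automatically
as k grows. A much weaker anchor would make warm starting a no-op under
full convergence; a much stronger one would pin personalized models to the
global one and erase the benefit of personalization. With `max_iter = 0`
the transfer fit returns the initializing coefficients untouched.

**Model families.** Six benchmark families: global; global warm-started
from itself (meaningful in the subsample sweep, where the initializer is
the full-training-data fit); subgroup models fit per predefined stratum,
cold or transfer-initialized; personalized models fit per target patient
on its k = round(k_fraction x |pool|) nearest neighbors (default
k_fraction = 0.10), cold or transfer-initialized. A neighborhood below 50
patients is refused; a single-class neighborhood falls back to the global
model's prediction, flagged in the fit metadata. No resampling or class
reweighting is used anywhere.

## Patient similarity

Distance between preprocessed patients is weighted Euclidean,
sqrt(sum_j w_j (x1_j - x2_j)^2), with nonnegative per-feature weights
normalized to mean 1. Retrieval is exact (brute-force) k-NN with ties
broken by ascending encounter id, which makes it invariant to pool
ordering; approximate indices are unnecessary at the scales involved.

Weight optimization is gradient-free: starting from uniform weights, each
iteration (i) draws a class-balanced probe subsample, (ii) multiplies each
coordinate in turn by 1 + step (default 0.5) and measures the change in
the probe-set AUROC of personalized models built under the perturbed
weights, (iii) proposes w <- w x exp(gain x delta / max|delta|),
clipped at zero and renormalized to mean 1, and (iv) accepts the proposal
only if it improves AUROC on the full probe set by more than `tol`;
rejected proposals leave the weights unchanged and the next iteration
draws a fresh subsample. The returned weights are the best scored, so
optimized weights can never score below uniform on the probe set, and the
accepted-step AUROC trace is non-decreasing by construction.
`probes_per_iter` (default 100) bounds the cost — each iteration fits
(d + 1) x probes personalized models — and is the knob to lower first on
large problems. This procedure is the package's own design; the interface
isolates it so an alternative optimizer can be swapped in.

## Evaluation

AUROC is the Mann-Whitney statistic (ties half credit), implemented
directly so it provably equals pair counting; AUPRC uses the
average-precision (step) convention — stated because interpolated
variants give different values; calibration error is the mean over 10
equal-frequency bins of (mean predicted - observed rate)^2, chosen
because its magnitudes on well-calibrated models (~1e-4) match how such
cohort calibration numbers are conventionally reported. Paired model
comparisons: the DeLong test (midrank structural components); a paired
bootstrap over test indices reporting wins/losses/ties out of B (default
20 000) with single-class resamples redrawn and counted; a two-sided z
test for independent estimates.

Cross-validation is stratified 5-fold; preprocessing, the global fit and
any weight optimization are confined to training folds, and out-of-fold
scores are pooled before metrics are computed — pooling keeps one paired
score vector per model, which is what the DeLong and bootstrap machinery
needs. The training-fraction sweep refits the global model on stratified
subsamples of an outer training split, cold versus warm-started from the
full-training-data fit, and evaluates on the untouched test split; at
fraction 1.0 the subsample is the identity, so the sweep's global entry
equals the plain global fit on that split. Alert-matched retrieval fixes
the alert budget at the true case count (the natural budget when
operating-point tables are unavailable) and reports the percent more
cases one model captures than another.

## Synthetic cohorts

The generator emulates the structure personalized modeling exploits, not
any particular hospital: n encounters in G latent subgroups (default 5,
uniform mix) with outcome log-odds beta_g = beta_global + delta_g, where
delta_g is N(0, tau^2) on a random support covering a `sparsity` fraction
of features (default 0.5) and zero elsewhere. A shared intercept is solved
numerically (Brent) so the expected prevalence over the realized design
hits the target, default 9.4% — the prevalence of hospital-acquired AKI in
the motivating cohort; demographics match a large US tertiary-care
inpatient population (age ~ N(55.5, 17.4) truncated to [18, 85], 54.8%
male). Features are half binary (Bernoulli, rates drawn in [0.1, 0.5]),
half continuous unit-normal. A small set of `n_informative` continuous
features carries subgroup-specific mean shifts (SD `separation`,
default 1.0): this is what makes subgroup membership visible to the
distance metric, the way admission diagnoses co-vary with the rest of a
real chart. Without some feature-subgroup association, no similarity
measure could retrieve subgroup-consistent neighborhoods and
personalization could not possibly help — the association strength is
therefore a primary experimental knob, not a nuisance. Missingness, when
requested, is completely at random and never touches labels.

Creatinine trajectories are built to make the labeler's job
well-defined: non-AKI stays get values whose 48-h rises stay below
0.15 x baseline < 0.3 mg/dL and never reach 1.5x baseline; AKI stays sit
flat at baseline, then jump by +0.35 mg/dL at an onset drawn uniformly in
[48, 120] h (with a plateau point 24 h before onset so the rolling window
always contains the reference), so the intended label and exact onset are
recovered by construction. Baselines are drawn in [0.5, 0.8] mg/dL, which
keeps every simulated stay eligible (eGFR above 60 for the simulated
demographics, early SCr below 1.3).

What passing tests on these cohorts does not show: robustness to
informative missingness, time-varying features, correlated medication
structure, coding drift, or subgroup structure that is invisible in the
features — all present in real EHR data and all out of scope here.

## Metaregression

Each personalized fit is one "study": effect = the target variable's
coefficient, variance = its squared SE (patients whose data did not record
the target are skipped), moderators = the patient's remaining covariates.
Random-effects metaregression uses weighted least squares with weights
1/(v_i + tau^2) and the DerSimonian-Laird method-of-moments residual
tau^2 = max(0, (Q - df)/tr(P)) — deterministic, standard, and verified in
the test suite against R's `metafor` (method = "DL") to 1e-6. SEs are
classical inverse-variance (not scale-adjusted WLS). Personalized models
share neighbors and are not independent; findings are treated as
hypothesis-generating and verified by a stratified refit (moderator
exposed vs unexposed, adjusted logistic coefficient and, for binary
targets, a raw 2x2 odds ratio with Haldane-Anscombe +0.5 correction on
zero cells) with a z test on the stratum difference. No cluster-robust
correction is attempted, and no multiplicity control is applied across
candidate moderators.

## Importance and heterogeneity measures

"AUROC gain" is permutation importance on AUROC: base AUROC minus the
mean over R = 20 seeded permutations of the feature's column. "Interclass
score difference" passes the single-feature contribution through the
logistic link with all other features held at their population mean and
takes |mean over cases - mean over controls| — one admissible reading of
a score-spread measure, stated explicitly because others exist. Subgroup
heterogeneity is the mean absolute pairwise Pearson correlation among the
top-k (default 50) important predictors within the subgroup, constant
columns dropped with a log entry. Relative-effect matrices divide
gain differences by the population gain and report a missing cell on zero
denominators. The coefficient of variation across personalized fits is
100 x sample SD / |mean| and is undefined at mean zero.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale, chosen so
each experiment's effect is far from its decision boundary while the
whole suite stays cheap: cohorts of 1 000-20 000 encounters with 5-50
features stand in for the motivating 76 957 x 1892 EHR matrix. The
heterogeneity ordering experiment uses n = 8000, d = 12, 4
subgroup-informative features, tau in {0, 2}; coefficient recovery uses
the full n = 20 000, d = 50, tau = 0.5 configuration; weight optimization
uses n = 1500, d = 12, prevalence 0.15 (probe AUROC on a 200-patient
probe set needs enough cases to be informative) with 4 iterations of 60
probes. L-BFGS runs to gtol 1e-10; all randomness flows from explicit
integer seeds through `numpy.random.default_rng`, and every documented
experiment is bit-reproducible under its seed.

## Known limitations

- The anchor-penalty transfer mechanism is one concrete realization of
  "initialize from the global model"; pure warm starting without the
  anchor would converge to the cold-start optimum.
- Personalized SEs come from penalized observed information and are
  mildly optimistic; downstream metaregression inherits this.
- The weight optimizer is a local, noisy search; it provably never
  degrades probe AUROC, but which features it credits can vary across
  seeds when several feature sets carry overlapping retrieval value.
- Calibration error depends on the binning convention; values are
  comparable only within this package's definition.
- Real-data ingestion expects the documented CSV schemas; no FHIR/OMOP
  support.
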