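# Methods

This note documents the statistical procedures `ehrms` implements, the
synthetic data the package uses to exercise them, and the design choices
made where the methodology left room.

## 1. Phenotype classification

### Model and penalty selection

The classifier is a logistic regression with an L1 penalty.  Features
are standardized internally; the penalty path runs over 100 log-spaced
values from λ_max — the smallest penalty at which every coefficient is
zero, λ_max = max_j |x_jᵀ(y − ȳ)| on the standardized design — down to
10⁻³·λ_max.  At each λ the fit's Bayesian Information Criterion is

    BIC(λ) = −2·loglik(β̂_λ) + df(λ)·ln n,

with df(λ) the number of non-zero coefficients (the standard LASSO
degrees-of-freedom estimate; the intercept is never penalized and never
counted).  The sparsest minimizer wins ties.  Coefficients are reported
back on the original feature scale so exported models are portable
across sites that cannot reproduce the training standardization.  The
L1 solver is scikit-learn's liblinear; the path construction, BIC
selection and everything downstream are implemented here.

Count features enter as log(1+count) by default (variance stabilization
for heavily skewed EHR counts); the transform is recorded per column and
"none" is selectable.  An absent count is an informative zero, never a
missing value.  Variables occurring in 10% or fewer of data-mart
patients are excluded before fitting (`at_most_excluded` rule).

### Operating point and metrics

The probability threshold is the ⌈0.95·m⌉-th order statistic of the m
control scores — the smallest t such that at least 95% of controls score
≤ t — and classification is strictly-greater-than t.  Sensitivity,
specificity, PPV and NPV come from the confusion table under that rule;
ratios with zero denominators are flagged as undefined rather than
silently zeroed.  AUC is the Mann–Whitney statistic with ties counted
one half.

### 0.632 bootstrap

For each of B_cv bootstrap resamples (default 200; smaller values are
used in tests) the model is refit on the resample, the threshold is
re-derived at 95% specificity *within that fit*, and every metric is
evaluated on the out-of-bag patients.  The bias-corrected estimate is
0.368·apparent + 0.632·(mean out-of-bag).  Replicates whose out-of-bag
set lacks a class are dropped and counted, not imputed.  Whether the
threshold should instead be fixed once on the full training data is
ambiguous in the source methodology; the per-fit choice is primary and
`threshold_mode="global"` provides the alternative.

Standard errors are a 1,000-replicate patient-level bootstrap of each
performance parameter at the full-data fit, with the threshold
re-derived inside every resample.  Re-running the entire nested
LASSO-BIC + 0.632 machinery inside each SE replicate would cost
~200,000 penalized path fits per variant and is not what any feasible
reading of the procedure requires; holding the fitted model (but not the
threshold) fixed captures the dominant sampling variability of the
metrics and reproduces the magnitude of published standard errors.

## 2. MSSS

MSSS places a patient's EDSS within the distribution of patients of
comparable disease duration.  Patients are grouped into integer-year
duration strata, capped at 30 years (longer durations pool); strata with
fewer than 10 patients merge into the nearest neighbouring stratum,
toward the smaller duration on ties.  Within a stratum of size n,

    MSSS = 10 · midrank(EDSS) / (n + 1) ∈ (0, 10),

with midranks averaging over EDSS ties.  EDSS measurements taken within
the first two years of symptom onset are excluded (strict `< 2.0` rule;
the boundary is retained) because the score is unstable that early.
This is the cohort-internal ("local") MSSS; `msss_global` accepts a
user-supplied duration × EDSS lookup table for scoring against an
external reference population when one is available.

## 3. Surrogate outcome derivation

Subjects are partitioned 50/30/20 into training/test/validation (floor
sizes, remainder to validation), stratified by outcome quintile so each
subgroup spans the outcome range (an unstratified fallback handles
degenerate outcomes).  In training, forward stepwise linear regression
runs inside each of 5 folds: variables are added greedily by in-fold
residual sum of squares and a fold stops when its held-out MSE stops
decreasing; the final selection is the variables chosen in a strict
majority (>k/2) of folds.  This CV-guarded majority-vote flavor was
chosen over plain greedy stepwise because it makes selection stable and
reproducible.  Configured demographic covariates are forced into every
model: sex and onset age for MSSS (never disease duration — MSSS already
adjusts for it), plus disease duration for BPF.

Coefficients are then re-estimated by OLS *on the test subgroup only*
(aliased columns dropped with a warning), and performance is the
adjusted R² of those coefficients' predictions on the validation
subgroup, 1 − (1−R²)(n−1)/(n−p−1).  The whole cycle repeats 100 times
from fresh splits; the mean ± SD of the validation adjusted R² is the
headline, and the per-repeat log makes the summary exactly
recomputable.  Failed repeats are excluded and counted, not retried.
EHR variables with a non-zero value in fewer than 10% of subjects are
removed beforehand (`strictly_less_excluded` — note the deliberate
asymmetry with the classifier's rule), and the final algorithms use a
40% frequency cut-off.  The exported deployment model
(`fit_surrogate_model`) freezes one designated split's selection + test
re-estimation rather than averaging coefficients across repeats; the
designated seed is recorded in the model JSON.

A known property of this estimator: because selection is CV-guarded and
the selected models are small (p ≈ 7 at n ≈ 1800), the training-set R²
is nearly unbiased for the population R², so the train-vs-validation
overfitting margin (~0.03) is comparable to the validation R²'s sampling
noise (SD ~0.03–0.04 at n_val ≈ 360).  The overfitting direction
therefore holds on average and in a clear majority of repeats, but not
in ~95% of individual repeats at these sample sizes.

## 4. Group validation

Observed severity is compared between progressive (PP/SP) and
relapsing-remitting patients by ANCOVA: OLS of the outcome on a group
indicator plus sex, onset age and disease duration, with group means
evaluated at the covariate grand means and the group-coefficient t-test
as the p-value.  Derived severity uses a Welch (unequal-variance)
two-sample t-test with no further adjustment, since the covariates are
already part of the derivation.  The discovery/validation split
(default fraction 329/542) is stratified by group with largest-remainder
allocation, preserving group proportions to within one patient.

## 5. Synthetic cohort generator

### Count model

Every count feature follows a negative binomial with log link:

    log μ_vi = log(baseline_v) + ms_fc_v·D_i + sev_v·S_i·D_i (+ H_i),

where D_i is the latent disease indicator (default prevalence 0.30,
consistent with a code-screened data mart), S_i ~ N(0,1) is the latent
severity of MS patients, and H_i is a shared utilization factor present
only in `signal_mode="shared"`.  The default mode keeps codified and
narrative channels conditionally independent given disease status.
Dispersion θ is per-variable (variance μ + μ²/θ) — EHR code counts are
heavily overdispersed.  Draws use the gamma–Poisson mixture.

Defaults were calibrated once against the published cohort's marginals
and discriminations: 73% female; follow-up log-normal with median 8.4
and quartiles ≈ [3.5, 13.7] years; MS diagnosis codes per MS patient
median ≈ 21 [7–46]; the code count alone discriminates at AUC ≈ 0.89,
the full codified and narrative channels at ≈ 0.93 each, and the
combination at ≈ 0.97 (higher than a real cohort's ≈ 0.96 because the
independent-signal mode removes between-channel redundancy).  Non-MS
baselines are deliberately non-trivial: data-mart controls carry
MS-related codes by construction of the screen.

The severity signal is concentrated in five columns (brain-MRI count,
neurologist-note count, and positive mentions of demyelination, gait
difficulty and spasticity) rather than spread thinly across all
features.  With diffuse weak severity effects, cross-validated variable
selection misses enough signal that the configured population R² is not
recoverable by the double-CV procedure — which would defeat the
generator's purpose of providing a recoverable ground truth.

### MS-Center subset and outcomes

A fraction (default 0.77) of true-MS patients is marked as MS-Center
patients and receives onset age (normal, mean 30, SD 8 years), disease
duration (log-normal, median 10 years), disease category, EDSS and BPF.
Progressive patients are the top `progressive_fraction` (default 0.11)
of a noisy severity score S + N(0, 0.8²), split 70/30 into SP/PP, so
progressive status concentrates in the upper severity range by
construction.  BPF decreases in severity and duration with Gaussian
noise, clipped into (0.5, 1).

EDSS derives from a latent G = c·S + √(1−c²)·ε mapped through
3.0 + 1.9·G, clipped to [0, 10] and rounded to the legal EDSS grid
(0, then 1.0–10.0 in half points).  The mixing coefficient c is
calibrated by bisection so that the *realized* squared correlation
between the best linear feature predictor of severity (an OLS fit of S
on the standardized log1p feature columns) and the MSSS produced by the
full pipeline — including EDSS clipping, half-point discretization and
duration-stratified ranking — equals `population_r2_msss` (default
0.40).  Calibrating against the realized pipeline rather than the
analytic Gaussian-rank attenuation √(3/π) matters: floor/ceiling ties in
EDSS otherwise leave the realized R² a few points short of the target.
Setting `edss_noise_sd` overrides the calibration (0 gives an EDSS
strictly monotone in S, useful for testing).

All randomness flows from a single master seed through named
`numpy.random.SeedSequence` child streams (`spawn_key=(k,)` with a fixed
integer per stage), so cohorts, subsets and note text are bit-identical
across regenerations with the same seed.

### Note-text fixtures

`generate_notes` plants each patient's mention counts into synthetic
sentences — one mention per sentence, negated mentions preceded by a
negation cue — shuffled into notes of ~6 sentences.  This guarantees the
planted (positive, negative) counts are exactly recoverable by the
extractor, making the text stage testable end to end.  It makes no
attempt at realistic prose, visit structure, or cue–term interleaving
within sentences.

### What the generator does not emulate

Real EHR data have temporal structure, missingness correlated with
utilization, coding-practice drift, cross-site vocabulary differences,
and narrative text far harder than dictionary matching.  Passing tests
on this generator demonstrates the statistical machinery is correct and
calibrated under its stated model — not that the pipeline would achieve
any particular performance on real records.

## 6. Mention extraction

Notes are lowercased and tokenized on non-alphanumeric characters;
sentences are delimited by periods and semicolons.  Dictionary surface
forms match longest-first, left to right, each token consumed once.  A
match counts as negated when a negation cue (single- or multi-token)
begins within a 6-token window before the match start in the same
sentence — a NegEx-style rule; the window is configurable.  There is no
stemming, abbreviation expansion, terminology-system lookup, or handling
of uncertainty/family-history attributes: dictionaries list surface
variants explicitly.

## 7. Problem sizes used in tests

The test suite exercises the pipeline at reduced but non-trivial sizes
chosen to keep the full suite fast while leaving every statistical check
well-powered: classifier checks at n = 500–2,000 with 15–30 inner
bootstrap replicates and 30–60 penalty-path points; the specificity
calibration at n = 5,000; variant ordering over 20 generator seeds at
n = 600; surrogate recovery at the reference n = 1,800 with 100 repeats;
group-direction checks over 10 seeds at 500 center patients.
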