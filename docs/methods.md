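# Methods

`chdsurv` implements an explainable survival-analysis workflow for
in-hospital mortality after pediatric congenital heart-disease (CHD)
surgery: a synthetic cohort generator, the preprocessing and
feature-engineering rules of the workflow, stratified repeated
cross-validation, three survival learners behind one risk contract,
Bayesian hyperparameter tuning, concordance evaluation, and cross-model
aggregated Shapley feature importance, both static and time-dependent.
This note records the models, the defaults and why they were chosen, and
what the synthetic data can and cannot show.

## Synthetic cohort

Real single-center CHD cohorts are not publicly shareable, so the package
ships a generator whose output has the statistical structure the analysis
assumes. Patients belong to four disease groups of decreasing severity —
UVHD I, UVHD II, BVHD cmplx., BVHD smpl. — with default sizes
50/111/291/850 (n = 1302).

Each patient carries two latent durations measured in days from surgery:

* **death time** `T ~ Weibull(k, λ_g) / exp(η)^(1/k)` with shared shape
  `k = 1` and a group-specific scale `λ_g`; `η = Σ β_j z_j` is a linear
  predictor over internally standardized covariates;
* **discharge time** `D ~ LogNormal(μ_g, σ_g)` with group medians
  17/14/10/6 days and spreads fitted to interquartile ranges.

Observed follow-up is `min(T, D)` recorded at 0.1-day resolution
(timestamp-derived fractional days); the patient is `deceased` iff
`T ≤ D`, otherwise discharge censors the observation. The scales `λ_g`
are calibrated by Monte-Carlo bisection (~78 000 patients at the true
group proportions) so that per-group mortality averages
62 / 7.2 / 9.6 / 0.7 %.

The planted log-hazard effects are, in decreasing order: post-surgery
creatinine maximum (β = 2.0 per sd), open thorax (0.9), circulatory
arrest (0.6), UVHD I membership (0.4, on top of the group baselines).
The creatinine magnitude is a calibrated quantity: it is set so that the
creatinine maximum is the dominant recoverable signal for tree-ensemble
attribution methods against the strong group-baseline signal that the
mortality targets impose. Urea shares a mild renal factor with
creatinine (correlation ≈ 0.25 on the log scale) — enough to be
clinically plausible, not enough to transfer the planted signal to an
effect-free proxy.

Lab series (creatinine, urea, C-reactive protein, leukocytes) are 4–8
lognormal draws per analyte within 72 h of surgery around a patient-level
latent mean; engineering reduces them to their clinically relevant
extremes. Missingness is MCAR with default rates 2.23 % (weight) and
0.08 % (height).

**What the generator does not emulate:** treatment policies, informative
(MNAR) missingness, time-varying risk, correlations between discharge
timing and covariates within a group, or real physiology. Passing the
recovery benchmarks therefore shows that the pipeline recovers a known
planted signal under realistic censoring and class imbalance — not that
it would rank features correctly on real clinical data.

## Preprocessing and feature engineering

1. **Imputation** — multivariate imputation by chained equations
   producing a single completed table: predictive-mean matching (linear
   regression, 5 donors) for continuous fields, logistic Bernoulli draws
   for binaries, 10 cycles, seeded. A single completed matrix (rather
   than multiple imputations with pooling) is used because the learners
   need one design matrix. Imputation is fitted on the whole cohort
   before splitting; this mild leakage mirrors the workflow order
   (engineering after imputation, split afterwards) and is confined to
   two low-missingness fields.
2. **Engineering** — weight is collapsed to a binary `weight < 2500 g`
   flag (raw weight, height, and age at admission are dropped as
   near-collinear with age at surgery); hospitalization history becomes
   the most severe past group under the severity ranking
   UVHD Ia > UVHD Ib > BVHD cmplx. > UVHD II/III > BVHD smpl.; lab series
   become 72 h extremes (max for creatinine, urea, CRP; min for
   leukocytes as a leukopenia marker). The result is exactly 19
   predictors plus the survival outcome.
3. **Outlier censoring** — follow-up times above the 99.5 % quantile of
   the whole cohort (linear-interpolation quantile) are truncated to the
   threshold and forced to censored.
4. **Correlation screen** — all continuous predictor pairs with
   |Pearson r| ≥ 0.7 are reported; the shipped predictor set yields an
   empty report on default synthetic data.

## Partitioning

Strata are the cross of 5 quantile bins of follow-up time × status ×
disease group (duplicate quantile edges collapse automatically, which
merges sparse bins). The 60/40 holdout split allocates the half-up
rounding of `0.6 · n_s` per stratum; singleton strata go to train. CV
folds are dealt round-robin: members are shuffled within stratum, strata
concatenated with event-containing strata first, and the fold counter
runs on across strata from a random offset. This guarantees fold sizes
within each stratum differ by ≤ 1 and that every fold receives an event
whenever at least k events exist.

## Survival models

All models expose `predict_risk` (higher = higher mortality risk); RSF
and CPH also expose survival functions.

* **RSF** — random survival forest (scikit-survival). Risk is the
  ensemble cumulative hazard summed over the unique training times (the
  standard ensemble mortality measure). Because the per-node survival
  arrays are large and attribution estimators evaluate tens of thousands
  of hybrid rows, prediction uses a precomputed per-leaf table plus the
  C-level tree traversal; this is numerically identical to the library
  path. Default configuration: 100 trees, depth 40, minimum node size
  20, mtry 2, sample fraction 0.63.
* **Boosted Cox** — xgboost with the Cox partial-likelihood objective.
  Risk is the boosted margin (log relative hazard). The boosting-round
  count is chosen by early stopping (500 patience) on a validation fold
  and logged. Defaults: learning rate 0.11, depth 5, subsample 0.5,
  colsample 0.8, min child weight 1.
* **CPH** — Cox proportional hazards (scikit-survival, Breslow ties and
  baseline hazard), fitted on the union of the two ML families' top-5
  features. Inside the pipeline a small ridge (α = 0.01) stabilizes
  small resampled folds against quasi-separation; the public `fit_cph`
  default is unpenalized.

Hyperparameter bounds follow the tuning table of the workflow (e.g.
learning rate (0.001, 0.2], mtry [2, 9], trees [100, 1000]); configs
reject out-of-bounds values.

## Hyperparameter optimization

Bayesian optimization maximizes the mean stratified 3-fold CV C-index.
Initialization draws distinct settings from the coarse min/max/step
lattice; proposals maximize the upper confidence bound
`μ(x) + κ σ(x)` (κ = 3.5) of a Gaussian-process surrogate (Matérn-5/2,
normalized inputs) over a random candidate sample (128 draws). Failed
evaluations are recorded as NaN and skipped by the surrogate. The full
profile is 50 init + 128 iterations; the reduced profile ships 16 + 8
with 32 candidate draws.

## Evaluation

Harrell's C-index with the classical definition: a pair is comparable
iff the earlier time is an event and the times differ; risk ties earn
half credit. Tied event times are excluded (documented tie-break; the
unit suite pins this against an all-pairs brute-force oracle and the
scikit-survival implementation). Repeated-CV performance is summarized
as mean ± sd (population sd, so a single model reports sd = 0) per
family, overall and per disease group; group subsets without comparable
pairs are reported as NaN.

## Attributions

The Shapley engine is estimator-agnostic over a value function that may
return scalars (risk) or curves (survival functions):

* **exact** — full subset enumeration for p ≤ 10, background-averaged
  (interventional) coalition values; additivity to machine precision.
* **sampling** — antithetic permutation pairs (a permutation and its
  reverse) sharing one background draw per observation. The base value
  is the mean model output over the drawn backgrounds, which makes
  per-observation additivity exact by telescoping; each cell carries a
  reported Monte-Carlo standard error estimated from the independent
  pair means. Default 64 permutations (8 in the reduced profile).
* **tree** — for the boosted-Cox family, xgboost's native
  path-dependent tree attribution (exact additivity on the margin
  scale).

The background set is always the training fold of the explained model,
so base values never see holdout information.

Aggregation over the 100 repeated-CV models is the elementwise mean per
observation and feature; feature rankings use the mean absolute
attribution with lexicographic tie-breaks. Time-dependent attributions
explain the predicted survival function on a grid of unique training
event times (quantile-thinned, default cap 200 points; 40 in the
reduced profile): per time point the feature attributions sum to
`S(t|x) − S̄(t)` where `S̄` is the background-average survival curve.
Global curves average over observations; aggregated-global curves then
average over models. They are computed for the RSF only — the
boosted-Cox learner predicts risk scores, not survival functions.
Attribution magnitudes are never compared across families (the risk
scales differ); cross-family statements use ranks.

## Desk-scale (reduced) profile

The full workflow at publication scale explains all holdout
observations with 64 permutations per model. The shipped reduced
profile — used by the test suite and the acceptance script — keeps the
cohort (n = 1302), the 60/40 split and the full 10×10 repeated CV, and
shrinks only estimator effort: tuning 16 + 8 evaluations, 8 sampling
permutations over a fixed 128-observation holdout subset per model,
time-dependent curves for the first 10 RSF models over 64 observations
with 4 permutations. These sizes keep a complete run near ten minutes
on one core while leaving the planted-signal recovery margins wide.

## Known limitations

* Single-imputation MICE; no between-imputation variance.
* The generator's group-wise covariate shifts are coarse
  (median/IQR-matched lognormals), not fitted distributions.
* Quasi-separation can defeat the unpenalized CPH on very small folds;
  the pipeline's ridge stabilizer changes coefficients slightly.
* The sampling attribution estimator's Monte-Carlo error at the reduced
  profile's 8 permutations is material for individual observations; only
  aggregates (mean |φ| over ≥ 128 observations) should be interpreted.
* Proportional-hazards structure is assumed both in the generator and in
  two of the three learners; violations are not modeled.
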