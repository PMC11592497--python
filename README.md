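# chdsurv

Explainable survival machine learning for post-surgery mortality in
pediatric congenital heart disease (CHD) cohorts.

## The problem

Children undergoing surgery for congenital heart defects die in hospital
at very different rates depending on the anatomy and the procedure —
from under 1 % for simple biventricular defects to over 60 % for
univentricular stage-I palliation in a most-recent-encounter cohort
design. Clinicians want prognostic models that (a) handle the survival
structure of the outcome — days from surgery to discharge or in-hospital
death, where discharge *censors* the observation — and (b) explain which
pre-, intra- and post-operative factors drive the predicted risk.

`chdsurv` implements that workflow end to end for a cohort of four
disease groups (UVHD I, UVHD II, BVHD cmplx., BVHD smpl.; default sizes
50/111/291/850, overall mortality ≈ 5.6 %):

* a **synthetic cohort generator** (Weibull death times with planted
  log-hazard effects, lognormal discharge censoring, 72 h lab series,
  MCAR missingness) so every stage is testable without patient data;
* **preprocessing**: chained-equation imputation, the feature-engineering
  rules yielding 19 predictors, 99.5 %-quantile follow-up outlier
  censoring, a |r| ≥ 0.7 correlation screen;
* **stratified partitioning**: 60/40 holdout and 10×10 repeated CV folds
  stratified on time quantiles × status × disease group;
* three **survival learners** behind one risk contract — random survival
  forest (RSF), gradient-boosted Cox (XGB), and Cox proportional hazards
  (CPH) on the union of the ML families' top-5 features;
* **Bayesian hyperparameter tuning** (Gaussian-process surrogate, UCB
  acquisition with κ = 3.5) over the bounded search space;
* **evaluation** with Harrell's concordance index
  `C = P(risk_i > risk_j | T_i < T_j, event_i)`, mean ± sd over the 100
  repeated-CV models, overall and per disease group;
* **attributions**: per-model Shapley values φ[i, d_j] of the holdout
  predictions (exact enumeration, antithetic permutation sampling with a
  reported Monte-Carlo tolerance, or native tree attributions), averaged
  across the l = 100 CV models into φ_agg[i, d_j] = (1/l) Σ_k φ_k[i, d_j];
  and time-dependent attribution curves φ_t[i, d_j] of the RSF survival
  function, averaged over observations (global) and then over models
  (aggregated global).

## Worked example

```python
from chdsurv import synthetic as syn, preprocessing as prep, partitioning as part, models as mod
from chdsurv.evaluation import harrell_c_index
from chdsurv import explain as ex

spec = syn.default_spec(seed=0)
raw = syn.inject_missingness(syn.generate_cohort(spec), spec.missingness_rates, seed=1)
eng = prep.engineer_features(prep.impute_chained(raw, seed=2))
eng, n_out, n_ev, thr = prep.censor_followup_outliers(eng)
print(f"censored {n_out} follow-up outliers ({n_ev} events) at {thr:.1f} days")
print(prep.cohort_summary(eng).groups)

X = prep.encode_design_matrix(eng)
t, e = prep.survival_arrays(eng)
g = eng["disease_group"].to_numpy()
train, test = part.stratified_partition(t, e, g, ratio=0.6, seed=3)
rsf = mod.fit_rsf(X.iloc[train], t[train], e[train], seed=4)
c = harrell_c_index(t[test], e[test], rsf.predict_risk(X.iloc[test]))
print(f"holdout C-index (RSF): {c:.3f}")
shap = ex.shap_attributions(rsf, X.iloc[test[:128]], X.iloc[train],
                            method="sampling", seed=5, n_permutations=16)
print(shap.mean_abs().sort_values(ascending=False).head(5).round(2))
```

prints

```
censored 7 follow-up outliers (0 events) at 61.5 days
                n  events  mortality_pct
UVHD I         50      31          62.00
UVHD II       111      10           9.01
BVHD cmplx.   291      25           8.59
BVHD smpl.    850       6           0.71
Total        1302      72           5.53
holdout C-index (RSF): 0.943
creatinine_max               4.69
days_admission_to_surgery    4.57
disease_group                3.61
age_at_surgery               3.19
open_thorax                  2.25
```

The cohort reproduces the intended group structure (62 % mortality in
UVHD I down to 0.7 % in BVHD smpl.), seven extreme follow-up times are
censored at the cohort's 99.5 % quantile, the forest discriminates
mortality well above chance on the held-out 40 %, and the mean absolute
Shapley attribution ranks the post-surgery creatinine maximum — the
strongest planted hazard effect — first.

The full orchestrated workflow (tuning → 10×10 repeated CV → holdout
evaluation → aggregated SHAP / time-dependent curves → CPH comparison) is
one call or one command:

```bash
chdsurv run --profile reduced --seed 1 --outdir my_run
```

It writes every artifact (engineered dataset, fold plan, tuning traces,
per-model C-indices, aggregated attribution tables, rank-frequency and
per-group force tables) as CSV plus a `manifest.json` with seeds, paths
and a config hash; reruns with the same seed are byte-identical.

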