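"""Imputation, feature engineering, outlier censoring, correlation screen,
descriptive summaries."""

import numpy as np
import pandas as pd
import pytest

from chdsurv import preprocessing as prep
from chdsurv import synthetic as syn


# --------------------------------------------------------------------------
# chained-equation imputation
# --------------------------------------------------------------------------


def test_impute_no_missing_is_identity():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [0, 1, 0]})
    pd.testing.assert_frame_equal(prep.impute_chained(df, seed=0), df)


def test_impute_observed_entries_unchanged():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"a": rng.normal(size=200), "b": rng.normal(size=200)})
    df.loc[rng.choice(200, 30, replace=False), "a"] = np.nan
    out = prep.impute_chained(df, seed=1)
    obs = df["a"].notna()
    assert np.array_equal(out.loc[obs, "a"], df.loc[obs, "a"])
    assert not out["a"].isna().any()


def test_impute_constant_column_fills_constant():
    df = pd.DataFrame({"a": [5.0] * 90 + [np.nan] * 10, "b": np.arange(100.0)})
    out = prep.impute_chained(df, seed=2)
    assert (out["a"] == 5.0).all()


def test_impute_deterministic_given_seed():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"a": rng.normal(size=300), "b": rng.normal(size=300)})
    df.loc[rng.choice(300, 60, replace=False), "a"] = np.nan
    pd.testing.assert_frame_equal(
        prep.impute_chained(df, seed=9), prep.impute_chained(df, seed=9)
    )


def test_impute_fully_missing_column_errors():
    df = pd.DataFrame({"a": [np.nan, np.nan], "b": [1.0, 2.0]})
    with pytest.raises(ValueError, match="fully missing"):
        prep.impute_chained(df, seed=0)


def test_impute_pmm_mean_recovery():
    """10 % MCAR on a Normal(5, 1) column: the completed column's mean stays
    within 0.2 of 5 at n = 2000, averaged over seeds."""
    means = []
    for s in range(10):
        rng = np.random.default_rng(1000 + s)
        a = rng.normal(5.0, 1.0, 2000)
        b = 0.5 * a + rng.normal(0, 1.0, 2000)
        df = pd.DataFrame({"a": a, "b": b})
        df.loc[rng.choice(2000, 200, replace=False), "a"] = np.nan
        out = prep.impute_chained(df, seed=s)
        means.append(out["a"].mean())
    assert abs(np.mean(means) - 5.0) < 0.2


# --------------------------------------------------------------------------
# feature engineering
# --------------------------------------------------------------------------


def _tiny_raw():
    spec = syn.default_spec(seed=42)
    return syn.generate_cohort(spec)


def test_engineered_has_19_predictors_no_missing(engineered):
    assert list(engineered.columns) == ["patient_id", *prep.PREDICTORS, "time", "status"]
    assert len(prep.PREDICTORS) == 19
    assert not engineered.isna().any().any()


def test_low_weight_flag_and_weight_dropped():
    raw = _tiny_raw()
    raw.loc[raw.index[0], "weight"] = 2499.0
    raw.loc[raw.index[1], "weight"] = 2500.0
    eng = prep.engineer_features(raw)
    assert eng["weight_lt_2500g"].iloc[0] == 1
    assert eng["weight_lt_2500g"].iloc[1] == 0
    for dropped in ("weight", "height", "age_at_admission"):
        assert dropped not in eng.columns


def test_history_feature_takes_most_severe_group():
    raw = _tiny_raw()
    raw.at[raw.index[0], "history_groups"] = ["BVHD smpl.", "UVHD Ia"]
    raw.at[raw.index[1], "history_groups"] = ["UVHD II/III", "BVHD cmplx."]
    raw.at[raw.index[2], "history_groups"] = []
    eng = prep.engineer_features(raw)
    assert eng["heart_disease_history"].iloc[0] == "UVHD Ia"
    assert eng["heart_disease_history"].iloc[1] == "BVHD cmplx."
    assert eng["heart_disease_history"].iloc[2] == "none"


def test_lab_extremes_from_series():
    raw = _tiny_raw()
    raw.at[raw.index[0], "lab_creatinine"] = [(4.0, 0.30), (30.0, 0.50), (70.0, 0.44)]
    raw.at[raw.index[1], "lab_leukocytes"] = [(10.0, 7.7)]
    eng = prep.engineer_features(raw)
    assert eng["creatinine_max"].iloc[0] == 0.50
    assert eng["leukocytes_min"].iloc[1] == 7.7


def test_lab_extremes_bound_raw_draws(engineered, raw_cohort):
    """min/max engineering: leukocytes_min <= every draw, creatinine_max >=
    every draw, per patient."""
    raw_vals = raw_cohort["lab_leukocytes"].map(lambda s: min(v for _, v in s))
    assert np.allclose(engineered["leukocytes_min"], raw_vals)
    raw_vals = raw_cohort["lab_creatinine"].map(lambda s: max(v for _, v in s))
    assert np.allclose(engineered["creatinine_max"], raw_vals)


def test_empty_lab_series_errors_with_patient():
    raw = _tiny_raw()
    raw.at[raw.index[0], "lab_urea"] = []
    with pytest.raises(ValueError, match="urea"):
        prep.engineer_features(raw)


def test_engineer_rejects_missing_values():
    raw = _tiny_raw()
    raw.loc[raw.index[0], "weight"] = np.nan
    with pytest.raises(ValueError, match="impute"):
        prep.engineer_features(raw)


# --------------------------------------------------------------------------
# follow-up outlier censoring
# --------------------------------------------------------------------------


def test_censoring_matches_bruteforce_on_known_times():
    times = np.arange(1.0, 201.0)
    df = pd.DataFrame({"time": times, "status": ["deceased"] * 100 + ["censored"] * 100})
    out, n_aff, n_ev, thr = prep.censor_followup_outliers(df, q=0.995)
    assert thr == pytest.approx(np.quantile(times, 0.995))
    expect_aff = int((times > thr).sum())
    assert n_aff == expect_aff
    assert n_ev == 0  # rows above threshold are all in the censored half
    assert (out["time"] <= thr).all()
    assert (out.loc[df["time"] > thr, "status"] == "censored").all()


def test_censoring_truncates_deceased_outlier_to_threshold():
    df = pd.DataFrame(
        {"time": [1.0] * 199 + [260.0], "status": ["censored"] * 199 + ["deceased"]}
    )
    out, n_aff, n_ev, thr = prep.censor_followup_outliers(df, q=0.5)
    assert n_aff == 1 and n_ev == 1
    assert out["time"].iloc[-1] == pytest.approx(thr)
    assert out["status"].iloc[-1] == "censored"


def test_censoring_noop_below_threshold():
    df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 3.0], "status": ["censored"] * 4})
    out, n_aff, n_ev, thr = prep.censor_followup_outliers(df, q=0.9)
    assert n_aff == 0 and n_ev == 0
    pd.testing.assert_frame_equal(out, df)


def test_censoring_never_increases_time_or_creates_events(engineered):
    out, *_ = prep.censor_followup_outliers(engineered, q=0.9)
    assert (out["time"] <= engineered["time"]).all()
    became_event = (engineered["status"] == "censored") & (out["status"] == "deceased")
    assert not became_event.any()


def test_censoring_invalid_quantile():
    df = pd.DataFrame({"time": [1.0], "status": ["censored"]})
    with pytest.raises(ValueError):
        prep.censor_followup_outliers(df, q=1.5)


# --------------------------------------------------------------------------
# correlation screen
# --------------------------------------------------------------------------


def test_identical_columns_reported_with_r_one():
    df = pd.DataFrame({"creatinine_max": np.arange(50.0), "urea_max": np.arange(50.0)})
    report = prep.prune_correlated(df, continuous=("creatinine_max", "urea_max"))
    assert len(report) == 1
    assert report["pearson_r"].iloc[0] == pytest.approx(1.0)


def test_independent_columns_give_empty_report():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({c: rng.normal(size=5000) for c in prep.CONTINUOUS_PREDICTORS})
    assert prep.prune_correlated(df).empty


def test_default_engineered_cohort_passes_screen(engineered):
    assert prep.prune_correlated(engineered).empty


# --------------------------------------------------------------------------
# cohort summary
# --------------------------------------------------------------------------


def test_summary_reproduces_reference_group_arithmetic():
    """(50, 31), (111, 8), (291, 28), (850, 6) -> 62.00 / 7.21 / 9.62 / 0.71
    per group and 73/1302 = 5.61 % overall."""
    rows = []
    for g, n, ev in [("UVHD I", 50, 31), ("UVHD II", 111, 8),
                     ("BVHD cmplx.", 291, 28), ("BVHD smpl.", 850, 6)]:
        for i in range(n):
            rows.append({"disease_group": g, "status": "deceased" if i < ev else "censored"})
    summary = prep.cohort_summary(pd.DataFrame(rows))
    got = summary.groups["mortality_pct"]
    assert got["UVHD I"] == 62.00
    assert got["UVHD II"] == 7.21
    assert got["BVHD cmplx."] == 9.62
    assert got["BVHD smpl."] == 0.71
    assert got["Total"] == 5.61
    assert summary.groups.loc["Total", "events"] == 73
    # totals equal the sum of the group rows exactly
    per_group = summary.groups.drop(index="Total")
    assert per_group["n"].sum() == summary.groups.loc["Total", "n"]
    assert per_group["events"].sum() == summary.groups.loc["Total", "events"]


def test_summary_zero_events():
    df = pd.DataFrame({"disease_group": ["UVHD I"] * 4, "status": ["censored"] * 4})
    summary = prep.cohort_summary(df)
    assert (summary.groups["mortality_pct"] == 0.0).all()
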