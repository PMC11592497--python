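"""Preprocessing and feature engineering for the CHD survival dataset.

Turns a raw cohort table into the 19-predictor modeling dataset:

1. chained-equation imputation of missing raw fields (predictive-mean
   matching for continuous variables, logistic draws for binaries),
2. feature engineering — binary low-birth-weight flag, most-severe
   disease-history feature, 72 h lab extremes (max for creatinine, urea and
   C-reactive protein; min for leukocytes as a leukopenia marker), dropping
   raw fields that are near-collinear with retained ones (weight, height,
   age at admission),
3. censoring of follow-up outliers at a high quantile of the whole cohort,
4. a correlation screen over the continuous predictors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .synthetic import DISEASE_GROUPS, LAB_ANALYTES

__all__ = [
    "PREDICTORS",
    "CONTINUOUS_PREDICTORS",
    "impute_chained",
    "engineer_features",
    "censor_followup_outliers",
    "prune_correlated",
    "cohort_summary",
    "encode_design_matrix",
]

#: The 19 predictors of the engineered dataset, in canonical column order.
PREDICTORS = (
    "sex",
    "weight_lt_2500g",
    "chrom_alterations",
    "disease_group",
    "heart_disease_history",
    "malformations",
    "pulm_hypertension",
    "days_admission_to_surgery",
    "n_previous_admissions",
    "crp_max",
    "leukocytes_min",
    "creatinine_max",
    "urea_max",
    "age_at_surgery",
    "aortic_cross_clamp_time",
    "circulatory_arrest",
    "hlm_category",
    "hypothermia_category",
    "open_thorax",
)

CONTINUOUS_PREDICTORS = (
    "days_admission_to_surgery",
    "n_previous_admissions",
    "crp_max",
    "leukocytes_min",
    "creatinine_max",
    "urea_max",
    "age_at_surgery",
    "aortic_cross_clamp_time",
)

#: Disease-history levels from least to most severe; severity ranking of the
#: groups is UVHD I(a/b) > BVHD cmplx. > UVHD II/III > BVHD smpl.
HISTORY_SEVERITY = ("none", "BVHD smpl.", "UVHD II/III", "BVHD cmplx.", "UVHD Ib", "UVHD Ia")

#: Disease groups ranked least to most severe, used for ordinal encoding.
GROUP_SEVERITY = ("BVHD smpl.", "UVHD II", "BVHD cmplx.", "UVHD I")


# --------------------------------------------------------------------------
# imputation
# --------------------------------------------------------------------------


def impute_chained(
    table: pd.DataFrame,
    n_iterations: int = 10,
    seed: int = 0,
    columns: Sequence[str] | None = None,
    n_donors: int = 5,
) -> pd.DataFrame:
    """Multivariate imputation by chained equations, single completed table.

    Continuous columns are imputed by predictive-mean matching (linear
    regression on the other numeric columns, then a random draw from the
    ``n_donors`` observed values whose predictions are closest); binary
    columns by a logistic-regression Bernoulli draw.  Observed entries are
    never modified, and the result is deterministic given *seed*.

    Parameters
    ----------
    table
        Input table; only numeric columns participate (as targets and as
        predictors).  Non-numeric columns pass through untouched.
    n_iterations
        Number of chained-equation cycles.
    columns
        Columns to impute; default: every numeric column containing NaN.
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    numeric = [c for c in out.columns if pd.api.types.is_numeric_dtype(out[c])]
    if columns is None:
        columns = [c for c in numeric if out[c].isna().any()]
    else:
        columns = list(columns)
    for c in columns:
        if out[c].isna().all():
            raise ValueError(f"column {c!r} is fully missing and cannot be imputed")
    if not columns:
        return out

    miss = {c: out[c].isna().to_numpy() for c in columns}
    # mean/mode starting values
    for c in columns:
        obs = out[c].dropna()
        is_binary = set(obs.unique()) <= {0, 1}
        fill = obs.mode().iloc[0] if is_binary else obs.mean()
        out.loc[miss[c], c] = fill

    X_all = out[numeric].to_numpy(float)
    col_idx = {c: numeric.index(c) for c in numeric}

    for _ in range(int(n_iterations)):
        for c in columns:
            m = miss[c]
            if not m.any():
                continue
            j = col_idx[c]
            others = [k for k in range(len(numeric)) if k != j]
            Xo = X_all[~m][:, others]
            yo = X_all[~m, j]
            Xm = X_all[m][:, others]
            uniq = np.unique(yo)
            if len(uniq) == 1:
                X_all[m, j] = uniq[0]
                continue
            if set(uniq) <= {0.0, 1.0}:
                clf = LogisticRegression(max_iter=200)
                clf.fit(Xo, yo)
                p = clf.predict_proba(Xm)[:, 1]
                X_all[m, j] = (rng.random(m.sum()) < p).astype(float)
            else:
                reg = LinearRegression().fit(Xo, yo)
                pred_obs = reg.predict(Xo)
                pred_mis = reg.predict(Xm)
                # predictive-mean matching against the n_donors closest donors
                order = np.argsort(pred_obs, kind="stable")
                sorted_pred = pred_obs[order]
                pos = np.searchsorted(sorted_pred, pred_mis)
                k = min(n_donors, len(yo))
                donors = np.empty(m.sum())
                for i, p_ in enumerate(pos):
                    lo = max(0, min(p_ - k, len(yo) - 2 * k))
                    hi = min(len(yo), lo + 2 * k)
                    window = order[lo:hi]
                    d = np.abs(pred_obs[window] - pred_mis[i])
                    nearest = window[np.argsort(d, kind="stable")[:k]]
                    donors[i] = yo[rng.choice(nearest)] if len(nearest) > 1 else yo[nearest[0]]
                X_all[m, j] = donors

    for c in columns:
        out[c] = X_all[:, col_idx[c]]
    return out


# --------------------------------------------------------------------------
# feature engineering
# --------------------------------------------------------------------------


def _lab_extreme(series: Iterable[tuple[float, float]], fn, patient: str, analyte: str) -> float:
    vals = [v for h, v in series if 0.0 <= h <= 72.0]
    if not vals:
        raise ValueError(f"patient {patient}: empty 72 h lab series for {analyte!r}")
    return float(fn(vals))


def _most_severe_history(history: Sequence[str]) -> str:
    if not history:
        return "none"
    return max(history, key=HISTORY_SEVERITY.index)


def engineer_features(raw: pd.DataFrame) -> pd.DataFrame:
    """Build the 19-predictor modeling dataset from an imputed raw cohort.

    Expects no missing values (run :func:`impute_chained` first).  Weight is
    collapsed to the binary low-weight flag ``weight_lt_2500g``; the raw
    weight, height and age-at-admission columns are dropped (near-collinear
    with age at surgery).  Lab series are reduced to their 72 h extremes.
    The disease-history feature is the most severe past group.
    """
    core = [c for c in raw.columns if not c.startswith("_")]
    if raw[core].isna().any().any():
        bad = [c for c in core if raw[c].isna().any()]
        raise ValueError(f"raw cohort still has missing values in {bad}; impute first")

    out = pd.DataFrame(index=raw.index)
    out["patient_id"] = raw["patient_id"]
    out["sex"] = raw["sex"]
    out["weight_lt_2500g"] = (raw["weight"].astype(float) < 2500.0).astype(int)
    out["chrom_alterations"] = raw["chrom_alterations"].astype(int)
    out["disease_group"] = raw["disease_group"]
    out["heart_disease_history"] = raw["history_groups"].map(_most_severe_history)
    out["malformations"] = raw["malformations"].astype(int)
    out["pulm_hypertension"] = raw["pulm_hypertension"].astype(int)
    out["days_admission_to_surgery"] = raw["days_admission_to_surgery"].astype(float)
    out["n_previous_admissions"] = raw["n_previous_admissions"].astype(int)

    extremes = {"creatinine": max, "urea": max, "crp": max, "leukocytes": min}
    names = {"creatinine": "creatinine_max", "urea": "urea_max", "crp": "crp_max", "leukocytes": "leukocytes_min"}
    for analyte in LAB_ANALYTES:
        fn = extremes[analyte]
        out[names[analyte]] = [
            _lab_extreme(series, fn, pid, analyte)
            for pid, series in zip(raw["patient_id"], raw[f"lab_{analyte}"])
        ]

    out["age_at_surgery"] = raw["age_at_surgery"].astype(float)
    out["aortic_cross_clamp_time"] = raw["aortic_cross_clamp_time"].astype(float)
    out["circulatory_arrest"] = raw["circulatory_arrest"].astype(int)
    out["hlm_category"] = raw["hlm_category"]
    out["hypothermia_category"] = raw["hypothermia_category"]
    out["open_thorax"] = raw["open_thorax"].astype(int)

    out["time"] = raw["followup_days"].astype(float)
    out["status"] = raw["status"]
    if (out["time"] < 0).any():
        raise ValueError("negative follow-up time encountered")
    return out[["patient_id", *PREDICTORS, "time", "status"]]


def censor_followup_outliers(
    dataset: pd.DataFrame, q: float = 0.995
) -> tuple[pd.DataFrame, int, int, float]:
    """Censor follow-up outliers at the *q* quantile of the whole cohort.

    The threshold is the linear-interpolation quantile of all follow-up
    times.  Times above it are truncated to the threshold and their status
    forced to ``censored``; nothing else changes.

    Returns ``(dataset, n_affected, n_events_affected, threshold)``.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"quantile must lie in (0, 1), got {q}")
    t = dataset["time"].to_numpy(float)
    threshold = float(np.quantile(t, q))  # linear interpolation between order stats
    affected = t > threshold
    n_affected = int(affected.sum())
    n_events = int((affected & (dataset["status"] == "deceased").to_numpy()).sum())
    out = dataset.copy()
    out.loc[affected, "time"] = threshold
    out.loc[affected, "status"] = "censored"
    return out, n_affected, n_events, threshold


def prune_correlated(
    dataset: pd.DataFrame,
    threshold: float = 0.7,
    continuous: Sequence[str] = CONTINUOUS_PREDICTORS,
) -> pd.DataFrame:
    """Report continuous predictor pairs with |Pearson r| >= threshold.

    The shipped predictor set is designed to produce an empty report on
    default synthetic data; a non-empty report flags a screening violation.
    """
    cols = [c for c in continuous if c in dataset.columns]
    corr = dataset[cols].corr(method="pearson")
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if abs(r) >= threshold:
                rows.append({"feature_a": a, "feature_b": b, "pearson_r": float(r)})
    return pd.DataFrame(rows, columns=["feature_a", "feature_b", "pearson_r"])


# --------------------------------------------------------------------------
# descriptive summaries
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSummary:
    """Per-group and total event counts plus per-variable descriptives."""

    groups: pd.DataFrame  # rows: group + "Total"; cols: n, events, mortality_pct
    variables: pd.DataFrame  # variable, statistic, value

    def to_json_dict(self) -> dict:
        return {
            "groups": self.groups.reset_index().to_dict(orient="records"),
            "variables": self.variables.to_dict(orient="records"),
        }


def cohort_summary(dataset: pd.DataFrame, group_col: str = "disease_group") -> CohortSummary:
    """Descriptive summary: group sizes, events, mortality percentages
    (rounded to two decimals), and mean ± sd / category counts per variable."""
    events = dataset["status"] == "deceased"
    rows = {}
    for g in [g for g in DISEASE_GROUPS if g in set(dataset[group_col])]:
        m = dataset[group_col] == g
        rows[g] = (int(m.sum()), int((m & events).sum()))
    rows["Total"] = (len(dataset), int(events.sum()))
    groups = pd.DataFrame(
        {
            "n": {g: n for g, (n, e) in rows.items()},
            "events": {g: e for g, (n, e) in rows.items()},
        }
    )
    groups["mortality_pct"] = (100.0 * groups["events"] / groups["n"]).round(2)

    var_rows = []
    for c in PREDICTORS:
        if c not in dataset.columns:
            continue
        col = dataset[c]
        if pd.api.types.is_numeric_dtype(col) and col.nunique() > 2:
            var_rows.append({"variable": c, "statistic": "mean", "value": float(col.mean())})
            var_rows.append({"variable": c, "statistic": "sd", "value": float(col.std())})
        else:
            for level, cnt in col.value_counts().sort_index().items():
                var_rows.append({"variable": c, "statistic": f"n[{level}]", "value": int(cnt)})
    return CohortSummary(groups=groups, variables=pd.DataFrame(var_rows))


# --------------------------------------------------------------------------
# numeric encoding for the learners
# --------------------------------------------------------------------------

_HLM_ORDER = {"0 min": 0, ">=1-<90 min": 1, ">=90 min": 2}
_HYPO_ORDER = {">32 C": 0, ">=28-<=32 C": 1, "<28 C": 2}


def encode_design_matrix(dataset: pd.DataFrame) -> pd.DataFrame:
    """Ordinal-encode the 19 predictors into a numeric design matrix.

    Ordered categoricals (disease group, history, bypass duration,
    hypothermia depth) are encoded by increasing severity so a single
    column per clinical concept is kept, mirroring how tree learners
    consumed integer-coded factors in the original workflow.
    """
    X = pd.DataFrame(index=dataset.index)
    for c in PREDICTORS:
        col = dataset[c]
        if c == "sex":
            X[c] = (col == "m").astype(int)
        elif c == "disease_group":
            X[c] = col.map({g: i for i, g in enumerate(GROUP_SEVERITY)}).astype(int)
        elif c == "heart_disease_history":
            X[c] = col.map({g: i for i, g in enumerate(HISTORY_SEVERITY)}).astype(int)
        elif c == "hlm_category":
            X[c] = col.map(_HLM_ORDER).astype(int)
        elif c == "hypothermia_category":
            X[c] = col.map(_HYPO_ORDER).astype(int)
        else:
            X[c] = col.astype(float)
    return X.astype(float)


def survival_arrays(dataset: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(time, event-indicator) arrays from an engineered dataset."""
    return (
        dataset["time"].to_numpy(float),
        (dataset["status"] == "deceased").to_numpy(bool),
    )
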