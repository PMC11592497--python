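"""Harrell's concordance index and repeated-CV performance aggregation.

The C-index is the fraction of comparable patient pairs ranked correctly by
the risk score.  A pair is comparable iff the earlier observed time is an
event and the two times are not tied; risk ties earn half credit (the
classical Harrell definition — tied event times are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["harrell_c_index", "evaluate_ensemble", "summarize_risk_sets", "PerformanceSummary"]


def harrell_c_index(time, status, risk) -> float:
    """Concordance between risk scores and observed survival.

    Parameters
    ----------
    time, status, risk
        Equal-length vectors; *status* is boolean (or the strings
        ``deceased``/``censored``), *risk* is "higher = riskier".

    Raises
    ------
    ValueError
        If the vectors disagree in length or no comparable pair exists.
    """
    t = np.asarray(time, float)
    s = np.asarray(status)
    if s.dtype.kind in "OU":
        s = s == "deceased"
    s = s.astype(bool)
    r = np.asarray(risk, float)
    if not (len(t) == len(s) == len(r)):
        raise ValueError("time, status and risk must have equal length")

    # vectorized over event rows: pair (i, j) comparable iff t_i < t_j, event_i
    conc = 0.0
    n_pairs = 0
    for i in np.flatnonzero(s):
        comparable = t > t[i]
        n_pairs += int(comparable.sum())
        conc += float((r[i] > r[comparable]).sum()) + 0.5 * float((r[i] == r[comparable]).sum())
    if n_pairs == 0:
        raise ValueError("no comparable pairs (need an event with a later time)")
    return conc / n_pairs


@dataclass(frozen=True)
class PerformanceSummary:
    """Per model family: the C-index of every CV model on the holdout, its
    mean ± sd, and an optional per-disease-group breakdown."""

    per_model: pd.DataFrame  # family, model_id, group ("all" or group), c_index
    summary: pd.DataFrame  # family, group, mean_c_index, sd_c_index, n_models

    def mean_c(self, family: str, group: str = "all") -> float:
        row = self.summary[(self.summary["family"] == family) & (self.summary["group"] == group)]
        return float(row["mean_c_index"].iloc[0])


def evaluate_ensemble(
    models: dict[str, list],
    X,
    time,
    status,
    groups=None,
) -> PerformanceSummary:
    """Apply every CV model of every family to the holdout and summarize.

    *models* maps family name to a list of fitted ``RiskModel``s.  When
    *groups* is given, C-indices are additionally computed within each
    disease-group subset; a subset with no comparable pairs is reported as
    NaN rather than raising.
    """
    if not models or all(len(v) == 0 for v in models.values()):
        raise ValueError("need at least one model")
    risks = {
        family: np.array([m.predict_risk(X) for m in fam_models])
        for family, fam_models in models.items()
        if len(fam_models)
    }
    return summarize_risk_sets(risks, time, status, groups)


def summarize_risk_sets(
    risks: dict[str, np.ndarray],
    time,
    status,
    groups=None,
) -> PerformanceSummary:
    """Summarize precomputed holdout risk scores, per family.

    *risks* maps family to an ``(n_models, n_observations)`` array; this is
    the memory-light path used when models are evaluated in a streaming
    fashion and discarded."""
    t = np.asarray(time, float)
    s = np.asarray(status)
    if s.dtype.kind in "OU":
        s = s == "deceased"
    rows = []
    for family, fam_risks in risks.items():
        for mid, r in enumerate(np.atleast_2d(fam_risks)):
            rows.append({"family": family, "model_id": mid, "group": "all",
                         "c_index": harrell_c_index(t, s, r)})
            if groups is not None:
                g = np.asarray(groups)
                for gl in pd.unique(g):
                    m = g == gl
                    try:
                        c = harrell_c_index(t[m], s[m], r[m])
                    except ValueError:
                        c = np.nan
                    rows.append({"family": family, "model_id": mid, "group": str(gl), "c_index": c})
    per_model = pd.DataFrame(rows)
    summary = (
        per_model.groupby(["family", "group"], as_index=False)["c_index"]
        .agg(mean_c_index="mean", sd_c_index=lambda v: float(np.std(v, ddof=0)), n_models="count")
    )
    return PerformanceSummary(per_model=per_model, summary=summary)
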