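"""Shapley attributions for survival risk models, and their aggregation.

Per-model attributions explain a model's risk score (or survival function)
for each holdout observation relative to a background expectation taken
over the model's own training fold.  Three estimators are available:

``exact``
    Full subset enumeration (cost ``2^p``), restricted to p <= 10.
    Additivity holds to machine precision.
``sampling``
    Antithetic permutation sampling: each sampled permutation is paired
    with its reverse, and both walk a chain of hybrid instances between a
    drawn background row and the explained row.  The per-observation base
    value is the mean model output over the drawn background rows, which
    makes additivity exact by telescoping while the individual
    attributions carry Monte-Carlo error.
``tree``
    The boosted-Cox learner's native path-dependent tree attribution
    (xgboost's built-in contribution output); exact additivity on the
    margin scale.

Attributions of many cross-validation models are combined by elementwise
averaging over models (for risk-score attributions) and, for the
time-dependent curves, by averaging first over observations (global
curves) and then over models (aggregated global curves).

Risk scales differ between model families (log relative hazard vs
cumulative hazard), so attribution magnitudes are comparable within a
family only; cross-family statements are made on ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import RiskModel

__all__ = [
    "ShapMatrix",
    "AggregatedShap",
    "SurvShapCurves",
    "shap_attributions",
    "aggregate_shap_over_models",
    "survshap_curves",
    "global_survshap",
    "aggregate_survshap_over_models",
    "mean_abs_ranking",
    "top_k_rank_frequency",
    "group_force_summary",
    "default_time_grid",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class ShapMatrix:
    """Per-observation, per-feature attributions of one model's risk score.

    ``base + values.sum(axis=1)`` reproduces the model's prediction per
    observation (exactly for the exact/tree estimators, by telescoping for
    the sampling estimator)."""

    values: np.ndarray  # (n, p)
    base: np.ndarray  # (n,)
    feature_names: tuple[str, ...]
    model_id: str = ""
    predictions: np.ndarray | None = None
    #: Monte-Carlo standard error per cell (sampling estimator only).
    mc_se: np.ndarray | None = None

    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names)


@dataclass
class AggregatedShap:
    """Elementwise mean of per-model attributions across CV models."""

    values: np.ndarray  # (n, p)
    base: np.ndarray  # (n,)
    feature_names: tuple[str, ...]
    n_models: int

    def mean_abs(self) -> pd.Series:
        return pd.Series(np.abs(self.values).mean(axis=0), index=self.feature_names)

    def ranking(self) -> pd.Series:
        return mean_abs_ranking(self.mean_abs())


@dataclass
class SurvShapCurves:
    """Time-dependent attributions: one curve per observation and feature.

    ``values[i, j, :]`` is the attribution of feature ``j`` to the
    predicted survival function of observation ``i`` over ``grid``; the sum
    over features equals ``S(t | x_i)`` minus the background-average
    survival curve ``base[i, :]``."""

    values: np.ndarray  # (n, p, m)
    base: np.ndarray  # (n, m)
    grid: np.ndarray  # (m,)
    feature_names: tuple[str, ...]
    model_id: str = ""


# --------------------------------------------------------------------------
# the Shapley engine (value function -> attributions)
# --------------------------------------------------------------------------


def _hybrid(x: np.ndarray, b: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Row with masked features from x, the rest from b."""
    return np.where(mask, x, b)


def _exact_phi(
    f: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact Shapley values by subset enumeration (p <= 10).

    The value of a coalition S is the mean of ``f`` over rows that take S
    from the explained row and the rest from each background row.
    Returns ``(phi, base)`` where outputs of ``f`` may be vectors (curves).
    """
    n, p = X.shape
    if p > 10:
        raise ValueError(f"exact enumeration infeasible for p = {p} > 10; use method='sampling'")
    B = len(background)
    subsets = np.arange(2**p)
    masks = ((subsets[:, None] >> np.arange(p)) & 1).astype(bool)  # (2^p, p)

    # evaluate v(S) for all subsets, batched over (subset, obs, background)
    rows = []
    for mask in masks:
        for i in range(n):
            rows.append(_hybrid(X[i], background, mask))
    big = np.concatenate(rows, axis=0)  # (2^p * n * B, p)
    out = np.asarray(f(big), float)
    m = 1 if out.ndim == 1 else out.shape[1]
    out = out.reshape(2**p, n, B, m).mean(axis=2)  # v(S) per obs, (2^p, n, m)

    from math import factorial

    w = np.array([factorial(s) * factorial(p - 1 - s) / factorial(p) for s in range(p)])
    sizes = masks.sum(axis=1)
    phi = np.zeros((n, p, m))
    for si, mask in enumerate(masks):
        for j in range(p):
            if mask[j]:
                continue
            sj = si | (1 << j)
            phi[:, j, :] += w[sizes[si]] * (out[sj] - out[si])
    base = out[0]  # empty coalition: background average, (n, m) all rows equal
    if m == 1:
        return phi[:, :, 0], base[:, 0]
    return phi, base


def _sampling_phi(
    f: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Antithetic permutation-sampling Shapley values.

    Permutations are drawn in antithetic pairs (a permutation and its
    reverse); each pair shares one background row per observation.  The
    base value is the per-observation mean of ``f`` over the drawn
    background rows, so per-observation additivity is exact.
    """
    n, p = X.shape
    n_pairs = max(1, n_permutations // 2)
    perms = []
    for _ in range(n_pairs):
        fwd = rng.permutation(p)
        perms.append(fwd)
        perms.append(fwd[::-1])
    bg_idx = rng.integers(len(background), size=(n_pairs, n))

    phi = None
    phi_sq = None
    base_acc = None
    pair_contrib = None
    for q, perm in enumerate(perms):
        b = background[bg_idx[q // 2]]  # (n, p): pair shares the draw
        # chain of hybrids: step t has features perm[:t] from x
        masks = np.zeros((p + 1, p), dtype=bool)
        for t in range(1, p + 1):
            masks[t, perm[:t]] = True
        big = np.concatenate([np.where(masks[t], X, b) for t in range(p + 1)], axis=0)
        out = np.asarray(f(big), float)
        m = 1 if out.ndim == 1 else out.shape[1]
        out = out.reshape(p + 1, n, m)
        if phi is None:
            phi = np.zeros((n, p, m))
            phi_sq = np.zeros((n, p, m))
            base_acc = np.zeros((n, m))
        contrib = np.zeros((n, p, m))
        contrib[:, perm, :] = (out[1:] - out[:-1]).transpose(1, 0, 2)
        phi += contrib
        base_acc += out[0]
        if q % 2 == 0:
            pair_contrib = contrib
        else:
            pair_mean = 0.5 * (pair_contrib + contrib)
            phi_sq += pair_mean**2

    phi /= len(perms)
    base = base_acc / len(perms)
    # MC standard error from the n_pairs independent antithetic-pair means
    if n_pairs > 1:
        var = (phi_sq / n_pairs - phi**2) * n_pairs / (n_pairs - 1)
        se = np.sqrt(np.clip(var, 0.0, None) / n_pairs)
    else:
        se = np.full_like(phi, np.inf)
    if phi.shape[2] == 1:
        return phi[:, :, 0], base[:, 0], se[:, :, 0]
    return phi, base, se


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def _background_matrix(model: RiskModel, background) -> np.ndarray:
    if isinstance(background, pd.DataFrame):
        cols = list(model.feature_names) if model.feature_names else list(background.columns)
        background = background[cols].to_numpy(float)
    background = np.asarray(background, float)
    if background.size == 0:
        raise ValueError("background set must be non-empty")
    return background


def shap_attributions(
    model: RiskModel,
    X,
    background,
    method: str = "sampling",
    seed: int = 0,
    n_permutations: int = 64,
    max_background: int | None = 64,
    model_id: str = "",
) -> ShapMatrix:
    """Attribute each observation's risk score to the 19 features.

    *background* should be the training fold of the explained model (keeps
    holdout information out of the base value).  ``max_background``
    subsamples it for the exact estimator's expectation and the sampling
    estimator's draws.
    """
    Xm = X[list(model.feature_names)].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    bg = _background_matrix(model, background)
    rng = np.random.default_rng(seed)
    if max_background is not None and len(bg) > max_background:
        bg = bg[rng.choice(len(bg), size=max_background, replace=False)]
    names = model.feature_names or tuple(f"x{j}" for j in range(Xm.shape[1]))

    f = model._predict_risk
    mc_se = None
    if method == "exact":
        phi, base = _exact_phi(f, Xm, bg)
    elif method == "sampling":
        phi, base, mc_se = _sampling_phi(f, Xm, bg, n_permutations, rng)
    elif method == "tree":
        if model.kind != "boosted_cox":
            raise ValueError("method='tree' is only available for boosted_cox models")
        import xgboost as xgb

        bst = model.metadata["booster"]
        n_rounds = model.metadata["n_rounds"]
        contrib = bst.predict(
            xgb.DMatrix(Xm), pred_contribs=True, iteration_range=(0, max(n_rounds, 1))
        )
        phi, base = contrib[:, :-1], contrib[:, -1].copy()
        if n_rounds == 0:
            phi = np.zeros_like(phi)
            base = np.zeros_like(base)
    else:
        raise ValueError(f"unknown method {method!r}")
    return ShapMatrix(
        values=phi,
        base=base,
        feature_names=tuple(names),
        model_id=model_id,
        predictions=model.predict_risk(Xm),
        mc_se=mc_se,
    )


def aggregate_shap_over_models(matrices: Sequence[ShapMatrix]) -> AggregatedShap:
    """Average attributions elementwise over CV models (same observations)."""
    if len(matrices) == 0:
        raise ValueError("need at least one ShapMatrix")
    shape = matrices[0].values.shape
    names = matrices[0].feature_names
    for m in matrices[1:]:
        if m.values.shape != shape or m.feature_names != names:
            raise ValueError("ShapMatrix shapes/features do not match")
    values = np.mean([m.values for m in matrices], axis=0)
    base = np.mean([m.base for m in matrices], axis=0)
    return AggregatedShap(values=values, base=base, feature_names=names, n_models=len(matrices))


def default_time_grid(time: np.ndarray, event: np.ndarray, max_points: int = 200) -> np.ndarray:
    """Unique event times of the training fold, quantile-thinned to at most
    ``max_points`` grid points."""
    t = np.unique(np.asarray(time, float)[np.asarray(event, bool)])
    if len(t) == 0:
        raise ValueError("no events: cannot build a time grid")
    if len(t) > max_points:
        t = np.quantile(t, np.linspace(0, 1, max_points))
        t = np.unique(t)
    return t


def survshap_curves(
    model: RiskModel,
    X,
    background,
    grid: np.ndarray,
    method: str = "sampling",
    seed: int = 0,
    n_permutations: int = 64,
    max_background: int | None = 64,
    model_id: str = "",
) -> SurvShapCurves:
    """Time-dependent attributions of the predicted survival function.

    Requires a model with the ``survival_function`` capability (the random
    survival forest and the Cox model; the boosted-Cox learner predicts
    risk scores only and is rejected).
    """
    if "survival_function" not in model.capabilities:
        raise ValueError(f"{model.kind} model lacks survival functions; cannot compute time-dependent attributions")
    grid = np.asarray(grid, float)
    Xm = X[list(model.feature_names)].to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    bg = _background_matrix(model, background)
    rng = np.random.default_rng(seed)
    if max_background is not None and len(bg) > max_background:
        bg = bg[rng.choice(len(bg), size=max_background, replace=False)]
    f = lambda M: model._predict_survival(M, grid)  # noqa: E731
    if method == "exact":
        phi, base = _exact_phi(f, Xm, bg)
    elif method == "sampling":
        phi, base, _ = _sampling_phi(f, Xm, bg, n_permutations, rng)
    else:
        raise ValueError(f"unknown method {method!r}")
    names = model.feature_names or tuple(f"x{j}" for j in range(Xm.shape[1]))
    return SurvShapCurves(values=phi, base=base, grid=grid, feature_names=tuple(names), model_id=model_id)


def global_survshap(curves: SurvShapCurves) -> pd.DataFrame:
    """Average curves over observations: one global curve per feature.

    Returns a tidy frame (feature, t, value)."""
    if curves.values.shape[0] == 0:
        raise ValueError("no observations to average")
    g = curves.values.mean(axis=0)  # (p, m)
    rows = [
        {"feature": feat, "t": float(t), "value": float(v)}
        for feat, row in zip(curves.feature_names, g)
        for t, v in zip(curves.grid, row)
    ]
    return pd.DataFrame(rows)


def aggregate_survshap_over_models(global_curves: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Average global curves over CV models on the shared grid."""
    if len(global_curves) == 0:
        raise ValueError("need at least one set of global curves")
    ref = global_curves[0][["feature", "t"]]
    for gc in global_curves[1:]:
        if not gc[["feature", "t"]].equals(ref):
            raise ValueError("global curves do not share (feature, t) layout")
    out = ref.copy()
    out["value"] = np.mean([gc["value"].to_numpy() for gc in global_curves], axis=0)
    return out


# --------------------------------------------------------------------------
# rankings and summaries
# --------------------------------------------------------------------------


def mean_abs_ranking(mean_abs: pd.Series) -> pd.Series:
    """Rank features by mean |phi| descending, ties broken by feature name
    (lexicographic), rank 1 = most important."""
    order = sorted(mean_abs.index, key=lambda f_: (-mean_abs[f_], f_))
    return pd.Series(np.arange(1, len(order) + 1), index=order)


def top_k_rank_frequency(mean_abs_tables: Sequence[pd.Series], k: int = 5) -> pd.Series:
    """How many CV models place each feature in their top-k by mean |phi|."""
    if len(mean_abs_tables) == 0:
        raise ValueError("need at least one per-model table")
    counts = pd.Series(0, index=mean_abs_tables[0].index)
    for tab in mean_abs_tables:
        ranks = mean_abs_ranking(tab)
        counts[ranks[ranks <= k].index] += 1
    return counts.sort_values(ascending=False)


def group_force_summary(
    agg: AggregatedShap,
    groups: Sequence[str],
    valid_groups: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean signed aggregated attribution per disease group and feature
    (the data behind per-group force plots)."""
    g = np.asarray(groups)
    if len(g) != agg.values.shape[0]:
        raise ValueError("group labels and attributions disagree in length")
    if valid_groups is not None:
        unknown = set(g) - set(valid_groups)
        if unknown:
            raise ValueError(f"unknown group label(s): {sorted(unknown)}")
    rows = []
    for gl in pd.unique(g):
        m = g == gl
        means = agg.values[m].mean(axis=0)
        for feat, v in zip(agg.feature_names, means):
            rows.append({"group": str(gl), "feature": feat, "mean_phi": float(v)})
    return pd.DataFrame(rows)


def shap_long_frame(matrices: Sequence[ShapMatrix]) -> pd.DataFrame:
    """Long-format export (observation, feature, value, model_id)."""
    frames = []
    for mat in matrices:
        n, p = mat.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "observation": np.repeat(np.arange(n), p),
                    "feature": np.tile(mat.feature_names, n),
                    "value": mat.values.ravel(),
                    "model_id": mat.model_id,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
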