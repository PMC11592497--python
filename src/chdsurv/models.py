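"""The three risk models behind one prediction contract.

* ``rsf`` — random survival forest (scikit-survival); risk score is the
  ensemble cumulative hazard summed over the training event-time grid
  (the classical ensemble mortality measure).
* ``boosted_cox`` — gradient boosting with the Cox partial-likelihood
  objective (xgboost, ``survival:cox``); risk score is the boosted linear
  predictor on the log-relative-hazard scale, with early stopping on a
  validation fold.
* ``cph`` — Cox proportional hazards regression (scikit-survival, Breslow
  ties and baseline hazard) on a feature subset; risk score is the linear
  predictor.

All risk scores are "higher = higher mortality risk"; scales differ across
families, so only rankings are comparable.  RSF and CPH additionally expose
survival functions, the prerequisite for time-dependent attributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sksurv.ensemble import RandomSurvivalForest
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "RSFConfig",
    "BoostedCoxConfig",
    "RiskModel",
    "fit_rsf",
    "fit_boosted_cox",
    "fit_cph",
]


def _check_bounds(name: str, value, lo, hi, lo_open: bool = False) -> None:
    ok = (lo < value if lo_open else lo <= value) and value <= hi
    if not ok:
        bra = "(" if lo_open else "["
        raise ValueError(f"{name} = {value} outside bounds {bra}{lo}, {hi}]")


@dataclass(frozen=True)
class RSFConfig:
    """Random-survival-forest hyperparameters (bounds of the tuning space).

    Defaults are the tuned setting of the reference workflow:
    100 trees, depth 40, minimum node size 20, mtry 2, sample fraction 0.63.
    """

    num_trees: int = 100
    max_depth: int = 40
    mtry: int = 2
    min_node_size: int = 20
    sample_fraction: float = 0.63

    def validate(self) -> None:
        _check_bounds("num_trees", self.num_trees, 100, 1000)
        _check_bounds("max_depth", self.max_depth, 1, 40)
        _check_bounds("mtry", self.mtry, 2, 9)
        _check_bounds("min_node_size", self.min_node_size, 1, 20)
        _check_bounds("sample_fraction", self.sample_fraction, 0.3, 1.0)


@dataclass(frozen=True)
class BoostedCoxConfig:
    """Boosted-Cox hyperparameters.  Defaults are the tuned setting of the
    reference workflow (learning rate 0.11, depth 5, subsample 0.5,
    colsample 0.8, min child weight 1); ``num_rounds`` is a cap — the
    realized round count is chosen by early stopping and logged."""

    max_depth: int = 5
    learning_rate: float = 0.11
    subsample: float = 0.5
    colsample_bytree: float = 0.8
    min_child_weight: float = 1.0
    num_rounds: int = 5000
    early_stopping_rounds: int | None = 500

    def validate(self) -> None:
        _check_bounds("max_depth", self.max_depth, 1, 40)
        _check_bounds("learning_rate", self.learning_rate, 0.001, 0.2, lo_open=True)
        _check_bounds("subsample", self.subsample, 0.3, 1.0)
        _check_bounds("colsample_bytree", self.colsample_bytree, 0.3, 1.0)
        _check_bounds("min_child_weight", self.min_child_weight, 0.0, 10.0)
        if self.num_rounds < 0:
            raise ValueError(f"num_rounds must be >= 0, got {self.num_rounds}")


@dataclass
class RiskModel:
    """Uniform wrapper: ``predict_risk`` always; survival functions where
    the underlying learner supports them."""

    kind: str  # {"rsf", "boosted_cox", "cph"}
    capabilities: frozenset
    _predict_risk: callable = field(repr=False)
    _predict_survival: callable | None = field(default=None, repr=False)
    event_times: np.ndarray | None = None
    feature_names: tuple[str, ...] = ()
    metadata: dict = field(default_factory=dict)

    def predict_risk(self, X) -> np.ndarray:
        """One finite risk score per row; higher means higher mortality."""
        r = np.asarray(self._predict_risk(_as_matrix(X, self.feature_names)), float)
        if not np.all(np.isfinite(r)):
            raise ValueError("non-finite risk score produced")
        return r

    def predict_survival(self, X, times: np.ndarray) -> np.ndarray:
        """Survival probabilities, shape (n, len(times))."""
        if "survival_function" not in self.capabilities:
            raise ValueError(f"{self.kind} model does not expose survival functions")
        return self._predict_survival(_as_matrix(X, self.feature_names), np.asarray(times, float))


def _as_matrix(X, feature_names) -> np.ndarray:
    if isinstance(X, pd.DataFrame):
        if feature_names:
            X = X[list(feature_names)]
        return X.to_numpy(float)
    return np.asarray(X, float)


def _surv_y(time: np.ndarray, event: np.ndarray):
    return Surv.from_arrays(np.asarray(event, bool), np.asarray(time, float))


def _require_events(event: np.ndarray, minimum: int = 2) -> None:
    if int(np.asarray(event, bool).sum()) < minimum:
        raise ValueError(f"training data needs >= {minimum} events")


def _feature_names(X) -> tuple[str, ...]:
    return tuple(X.columns) if isinstance(X, pd.DataFrame) else ()


def fit_rsf(
    X,
    time: np.ndarray,
    event: np.ndarray,
    config: RSFConfig = RSFConfig(),
    seed: int = 0,
) -> RiskModel:
    """Fit a random survival forest.

    Risk is the cumulative hazard summed over the unique training event
    times; survival functions come from the ensemble Nelson-Aalen /
    Kaplan-Meier aggregation on that grid.
    """
    config.validate()
    _require_events(event)
    names = _feature_names(X)
    Xm = _as_matrix(X, names)
    rsf = RandomSurvivalForest(
        n_estimators=config.num_trees,
        max_depth=config.max_depth,
        max_features=min(config.mtry, Xm.shape[1]),
        min_samples_leaf=config.min_node_size,
        max_samples=config.sample_fraction if config.sample_fraction < 1.0 else None,
        bootstrap=True,
        n_jobs=1,
        random_state=int(seed),
    )
    rsf.fit(Xm, _surv_y(time, event))
    grid = rsf.unique_times_

    # Per-leaf ensemble values precomputed once: prediction then only needs
    # the C-level tree traversal (apply), which keeps the thousands of
    # hybrid-row evaluations of the attribution estimators tractable.
    leaf_risk = [est.tree_.value[:, :, 0].sum(axis=1) for est in rsf.estimators_]

    def risk(Xq):
        Xq = np.ascontiguousarray(Xq, dtype=np.float32)
        acc = np.zeros(len(Xq))
        for est, lr in zip(rsf.estimators_, leaf_risk):
            acc += lr[est.tree_.apply(Xq)]
        return acc / len(rsf.estimators_)

    def survival(Xq, times):
        Xq = np.ascontiguousarray(Xq, dtype=np.float32)
        # step-function lookup of the requested times on the training grid
        idx = np.searchsorted(grid, times, side="right") - 1
        inside = idx >= 0
        acc = np.zeros((len(Xq), len(times)))
        for est in rsf.estimators_:
            node_surv = est.tree_.value[:, idx[inside], 1]
            acc[:, inside] += node_surv[est.tree_.apply(Xq)]
        acc /= len(rsf.estimators_)
        acc[:, ~inside] = 1.0  # before the first grid point: S = 1
        return acc

    return RiskModel(
        kind="rsf",
        capabilities=frozenset({"risk", "survival_function"}),
        _predict_risk=risk,
        _predict_survival=survival,
        event_times=grid,
        feature_names=names,
        metadata={"config": config.__dict__, "seed": int(seed)},
    )


def fit_boosted_cox(
    X,
    time: np.ndarray,
    event: np.ndarray,
    config: BoostedCoxConfig = BoostedCoxConfig(),
    validation: tuple | None = None,
    seed: int = 0,
) -> RiskModel:
    """Fit gradient-boosted Cox regression with optional early stopping.

    *validation* is ``(X_val, time_val, event_val)``; required whenever
    ``early_stopping_rounds`` is set.  Risk scores are the boosted margin
    (log relative hazard).
    """
    config.validate()
    _require_events(event)
    names = _feature_names(X)
    Xm = _as_matrix(X, names)
    ylab = np.where(np.asarray(event, bool), np.asarray(time, float), -np.asarray(time, float))
    dtrain = xgb.DMatrix(Xm, label=ylab)
    params = {
        "objective": "survival:cox",
        "max_depth": int(config.max_depth),
        "eta": float(config.learning_rate),
        "subsample": float(config.subsample),
        "colsample_bytree": float(config.colsample_bytree),
        "min_child_weight": float(config.min_child_weight),
        "seed": int(seed) % (2**31),
        "nthread": 1,
    }
    evals, kwargs = [], {}
    if config.early_stopping_rounds is not None and config.num_rounds > 0:
        if validation is None:
            raise ValueError("early stopping requested but no validation set provided")
        Xv, tv, ev = validation
        yv = np.where(np.asarray(ev, bool), np.asarray(tv, float), -np.asarray(tv, float))
        evals = [(xgb.DMatrix(_as_matrix(Xv, names), label=yv), "validation")]
        kwargs["early_stopping_rounds"] = int(config.early_stopping_rounds)
    bst = xgb.train(
        params,
        dtrain,
        num_boost_round=int(config.num_rounds),
        evals=evals,
        verbose_eval=False,
        **kwargs,
    )
    best_rounds = getattr(bst, "best_iteration", None)
    n_rounds = int(best_rounds) + 1 if best_rounds is not None else int(config.num_rounds)

    def risk(Xq):
        if n_rounds == 0:
            return np.zeros(len(Xq))
        return bst.predict(
            xgb.DMatrix(Xq), output_margin=True, iteration_range=(0, n_rounds)
        )

    model = RiskModel(
        kind="boosted_cox",
        capabilities=frozenset({"risk"}),
        _predict_risk=risk,
        feature_names=names,
        metadata={"config": config.__dict__, "seed": int(seed), "n_rounds": n_rounds},
    )
    model.metadata["booster"] = bst
    return model


def fit_cph(
    X,
    time: np.ndarray,
    event: np.ndarray,
    features: Sequence[str] | None = None,
    alpha: float = 0.0,
) -> RiskModel:
    """Cox proportional hazards on a feature subset (Breslow ties).

    Warns when the number of events is below the number of features.
    Exposes coefficients, the Breslow baseline cumulative hazard, and hence
    survival functions.  ``alpha`` adds a small ridge penalty; useful on
    small resampled folds where monotone likelihood (quasi-separation)
    would otherwise prevent convergence.
    """
    if isinstance(X, pd.DataFrame) and features is not None:
        X = X[list(features)]
    names = _feature_names(X)
    Xm = _as_matrix(X, names)
    _require_events(event)
    n_events = int(np.asarray(event, bool).sum())
    if n_events < Xm.shape[1]:
        import warnings

        warnings.warn(
            f"only {n_events} events for {Xm.shape[1]} features; estimates may be unstable",
            stacklevel=2,
        )
    est = CoxPHSurvivalAnalysis(ties="breslow", alpha=float(alpha))
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            est.fit(Xm, _surv_y(time, event))
    except (np.linalg.LinAlgError, ValueError) as exc:
        raise ValueError(f"CPH fit failed (degenerate/collinear design?): {exc}") from exc
    grid = est.unique_times_

    def risk(Xq):
        return Xq @ est.coef_

    def survival(Xq, times):
        S = est.predict_survival_function(Xq, return_array=True)
        return _step_interp(grid, S, times)

    return RiskModel(
        kind="cph",
        capabilities=frozenset({"risk", "survival_function"}),
        _predict_risk=risk,
        _predict_survival=survival,
        event_times=grid,
        feature_names=names,
        metadata={"coef": dict(zip(names, est.coef_.tolist())) if names else est.coef_.tolist()},
    )


def _step_interp(grid: np.ndarray, S: np.ndarray, times: np.ndarray) -> np.ndarray:
    """Right-continuous step interpolation of survival curves; S(t) = 1 for
    t before the first grid point, constant after the last."""
    idx = np.searchsorted(grid, times, side="right") - 1
    out = np.ones((S.shape[0], len(times)))
    inside = idx >= 0
    out[:, inside] = S[:, idx[inside]]
    return out
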