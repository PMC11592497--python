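"""Bayesian hyperparameter optimization (GP surrogate, UCB acquisition).

The objective is the mean stratified 3-fold CV C-index of a learner at a
hyperparameter setting.  The optimizer is initialized with random draws
from a coarse grid (the tuning table's minimum/maximum/step lattice), then
proposes points by maximizing the upper confidence bound
``mu(x) + kappa * sigma(x)`` of a Gaussian-process surrogate (Matérn-5/2)
over a random candidate sample, with kappa defaulting to 3.5 to favour
exploration of the search space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern

__all__ = [
    "Parameter",
    "SearchSpace",
    "BayesOptConfig",
    "TuningResult",
    "bayesian_optimize",
    "rsf_search_space",
    "boosted_cox_search_space",
]


@dataclass(frozen=True)
class Parameter:
    """One tunable hyperparameter: bounds, integrality, and the coarse
    initialization lattice (grid_min/grid_max/grid_step)."""

    name: str
    lower: float
    upper: float
    integer: bool = False
    grid_min: float | None = None
    grid_max: float | None = None
    grid_step: float | None = None

    def grid_points(self) -> np.ndarray:
        if self.grid_min is None:
            return np.array([self.lower, self.upper])
        pts = np.arange(self.grid_min, self.grid_max + 1e-12, self.grid_step)
        return pts

    def validate(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: empty bounds [{self.lower}, {self.upper}]")
        for p in self.grid_points():
            if not (self.lower <= p <= self.upper):
                raise ValueError(f"{self.name}: grid point {p} outside bounds")


@dataclass(frozen=True)
class SearchSpace:
    parameters: tuple[Parameter, ...]

    def validate(self) -> None:
        for p in self.parameters:
            p.validate()

    def clip(self, x: np.ndarray) -> dict:
        """Continuous vector -> in-bounds (rounded where integral) setting."""
        out = {}
        for v, p in zip(x, self.parameters):
            v = float(np.clip(v, p.lower, p.upper))
            out[p.name] = int(round(v)) if p.integer else v
        return out

    def sample_grid(self, rng: np.random.Generator) -> dict:
        return {
            p.name: (int(v) if p.integer else float(v))
            for p, v in ((p, rng.choice(p.grid_points())) for p in self.parameters)
        }

    def sample_uniform(self, rng: np.random.Generator, size: int) -> np.ndarray:
        cols = [rng.uniform(p.lower, p.upper, size=size) for p in self.parameters]
        return np.column_stack(cols)

    def to_vector(self, setting: Mapping[str, float]) -> np.ndarray:
        return np.array([float(setting[p.name]) for p in self.parameters])


@dataclass(frozen=True)
class BayesOptConfig:
    """kappa: UCB exploration weight; n_sampling_runs: candidate draws per
    acquisition maximization; n_init: random-grid initializations."""

    kappa: float = 3.5
    n_sampling_runs: int = 128
    n_init: int = 50
    n_iterations: int = 128
    seed: int = 0

    def validate(self) -> None:
        if self.kappa <= 0:
            raise ValueError(f"kappa must be > 0, got {self.kappa}")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")


#: Budget-reduced profile for desk-scale runs.
REDUCED_BAYESOPT = dict(n_init=16, n_iterations=8, n_sampling_runs=32)


@dataclass
class TuningResult:
    best_setting: dict
    best_value: float
    trace: pd.DataFrame  # iteration, phase, value + one column per parameter

    def to_json_dict(self) -> dict:
        return {"best_setting": self.best_setting, "best_value": self.best_value}


def bayesian_optimize(
    objective: Callable[[Mapping[str, float]], float],
    space: SearchSpace,
    config: BayesOptConfig = BayesOptConfig(),
) -> TuningResult:
    """Maximize *objective* over *space*; returns best setting and trace.

    Failed evaluations (objective raising) are recorded as NaN in the trace
    and skipped by the surrogate; the search continues.  Deterministic
    given ``config.seed``.
    """
    space.validate()
    config.validate()
    rng = np.random.default_rng(config.seed)
    rows: list[dict] = []
    X_obs: list[np.ndarray] = []
    y_obs: list[float] = []

    def evaluate(setting: dict, phase: str, it: int):
        try:
            value = float(objective(setting))
        except Exception:  # noqa: BLE001 — a failed point must not kill the search
            value = np.nan
        rows.append({"iteration": it, "phase": phase, "value": value, **setting})
        if np.isfinite(value):
            X_obs.append(space.to_vector(setting))
            y_obs.append(value)

    seen = set()
    it = 0
    n_init = min(config.n_init, _grid_size(space))
    while it < n_init:
        setting = space.sample_grid(rng)
        key = tuple(setting.values())
        if key in seen:
            continue  # redraw duplicates: init points are distinct grid settings
        seen.add(key)
        evaluate(setting, "init", it)
        it += 1

    kernel = Matern(nu=2.5, length_scale=np.ones(len(space.parameters)))
    for _ in range(config.n_iterations):
        if len(y_obs) >= 2 and np.ptp(y_obs) > 0:
            Xn, lo, span = _normalize(np.array(X_obs), space)
            gp = GaussianProcessRegressor(
                kernel=kernel, alpha=1e-6, normalize_y=True, random_state=int(rng.integers(2**31))
            )
            import warnings

            from sklearn.exceptions import ConvergenceWarning

            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                gp.fit(Xn, np.array(y_obs))
            cand = space.sample_uniform(rng, config.n_sampling_runs)
            mu, sd = gp.predict((cand - lo) / span, return_std=True)
            best = cand[np.argmax(mu + config.kappa * sd)]
            setting = space.clip(best)
        else:
            setting = space.clip(space.sample_uniform(rng, 1)[0])
        evaluate(setting, "bayes", it)
        it += 1

    trace = pd.DataFrame(rows)
    finite = trace[np.isfinite(trace["value"])]
    if finite.empty:
        raise ValueError("every objective evaluation failed")
    best_row = finite.loc[finite["value"].idxmax()]
    best_setting = {
        p.name: (int(best_row[p.name]) if p.integer else float(best_row[p.name]))
        for p in space.parameters
    }
    return TuningResult(best_setting=best_setting, best_value=float(best_row["value"]), trace=trace)


def _grid_size(space: SearchSpace) -> int:
    n = 1
    for p in space.parameters:
        n *= len(p.grid_points())
    return n


def _normalize(X: np.ndarray, space: SearchSpace):
    lo = np.array([p.lower for p in space.parameters])
    hi = np.array([p.upper for p in space.parameters])
    span = hi - lo
    return (X - lo) / span, lo, span


def rsf_search_space() -> SearchSpace:
    """Random-survival-forest tuning space (bounds and init lattice)."""
    return SearchSpace(
        parameters=(
            Parameter("max_depth", 1, 40, integer=True, grid_min=1, grid_max=9, grid_step=4),
            Parameter("min_node_size", 1, 20, integer=True, grid_min=1, grid_max=9, grid_step=4),
            Parameter("mtry", 2, 9, integer=True, grid_min=2, grid_max=6, grid_step=2),
            Parameter("num_trees", 100, 1000, integer=True, grid_min=500, grid_max=1000, grid_step=500),
            Parameter("sample_fraction", 0.3, 1.0, grid_min=0.5, grid_max=0.8, grid_step=0.3),
        )
    )


def boosted_cox_search_space() -> SearchSpace:
    """Boosted-Cox tuning space (bounds and init lattice); the learning
    rate's lower bound is open at 0.001."""
    return SearchSpace(
        parameters=(
            Parameter("colsample_bytree", 0.3, 1.0, grid_min=0.5, grid_max=0.8, grid_step=0.3),
            Parameter("learning_rate", 0.001, 0.2, grid_min=0.01, grid_max=0.11, grid_step=0.05),
            Parameter("max_depth", 1, 40, integer=True, grid_min=1, grid_max=9, grid_step=4),
            Parameter("min_child_weight", 0.0, 10.0, grid_min=1, grid_max=9, grid_step=4),
            Parameter("subsample", 0.3, 1.0, grid_min=0.5, grid_max=0.8, grid_step=0.3),
        )
    )
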