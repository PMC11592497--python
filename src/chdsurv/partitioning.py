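"""Stratified holdout splitting and repeated cross-validation folds.

Survival data with a 5.6 % event rate cannot be split naively: random folds
easily end up with no deaths at all.  Strata are therefore built by
crossing quantile bins of the follow-up time with the event status and the
disease group, and observations are dealt to partitions within strata.
Event-containing strata are dealt first in a single global round-robin so
that events spread as evenly as arithmetic allows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["StrataDefinition", "FoldPlan", "build_strata", "stratified_partition", "repeated_cv_folds"]


@dataclass(frozen=True)
class StrataDefinition:
    """How strata are formed: time-quantile bins × status × group."""

    time_bins: int = 5
    use_status: bool = True
    use_group: bool = True

    def __post_init__(self):
        if self.time_bins < 1:
            raise ValueError(f"time_bins must be >= 1, got {self.time_bins}")


def build_strata(
    time: np.ndarray,
    status: np.ndarray,
    group: np.ndarray | None,
    strata: StrataDefinition,
) -> np.ndarray:
    """Integer stratum label per observation.

    Time bins are quantile cuts of the follow-up time; degenerate/empty bins
    collapse into their neighbours automatically because labels are formed
    from the realized bin of each observation.
    """
    time = np.asarray(time, float)
    n = len(time)
    edges = np.quantile(time, np.linspace(0, 1, strata.time_bins + 1))
    edges = np.unique(edges)  # merge empty/duplicate bins
    tb = np.clip(np.searchsorted(edges, time, side="right") - 1, 0, len(edges) - 2)
    keys = pd.DataFrame({"tb": tb})
    if strata.use_status:
        keys["st"] = np.asarray(status).astype(int)
    if strata.use_group and group is not None:
        keys["gr"] = pd.factorize(np.asarray(group))[0]
    return pd.factorize(pd.MultiIndex.from_frame(keys))[0]


def _ordered_deal(
    labels: np.ndarray,
    status: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Observation order for round-robin dealing: shuffled within stratum,
    event strata first, so a continuing deal balances events across folds."""
    n = len(labels)
    order = []
    strat_ids = np.unique(labels)
    # event strata first (status aggregated per stratum), then by label
    has_event = {s: bool(status[labels == s].any()) for s in strat_ids}
    for s in sorted(strat_ids, key=lambda s: (not has_event[s], s)):
        members = np.flatnonzero(labels == s)
        order.append(rng.permutation(members))
    return np.concatenate(order)


def stratified_partition(
    time: np.ndarray,
    status: np.ndarray,
    group: np.ndarray | None,
    ratio: float = 0.6,
    strata: StrataDefinition = StrataDefinition(),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Split indices into (train, test) at *ratio*, stratified.

    Within every stratum the train count is the half-up rounding of
    ``ratio * n_stratum`` (deviation < 1 observation); singleton strata go
    to train deterministically.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    status = np.asarray(status)
    if status.dtype.kind in "OU":
        status = status == "deceased"
    labels = build_strata(time, status, group, strata)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for s in np.unique(labels):
        members = np.flatnonzero(labels == s)
        if len(members) == 1:
            train.append(members)
            continue
        perm = rng.permutation(members)
        n_train = int(np.floor(ratio * len(members) + 0.5))
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    train_ids = np.sort(np.concatenate(train))
    test_ids = np.sort(np.concatenate(test)) if test else np.array([], int)
    return train_ids, test_ids


@dataclass(frozen=True)
class FoldPlan:
    """Fold assignments of a (repeated) stratified k-fold CV.

    ``assignment[r, i]`` is the test-fold index of observation ``i`` in
    repeat ``r``.  The same plan object is shared by all learners so that
    every model family sees identical folds.
    """

    k: int
    repeats: int
    assignment: np.ndarray  # shape (repeats, n), int fold ids in [0, k)
    seed: int = 0

    @property
    def n(self) -> int:
        return self.assignment.shape[1]

    def test_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment[repeat] == fold)

    def train_indices(self, repeat: int, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignment[repeat] != fold)

    def tasks(self):
        """Iterate all (repeat, fold) training tasks — k × repeats of them."""
        for r in range(self.repeats):
            for f in range(self.k):
                yield r, f

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"observation": i, "repeat": r, "fold": int(self.assignment[r, i])}
            for r in range(self.repeats)
            for i in range(self.n)
        ]
        return pd.DataFrame(rows)


def repeated_cv_folds(
    time: np.ndarray,
    status: np.ndarray,
    group: np.ndarray | None,
    k: int = 10,
    repeats: int = 10,
    strata: StrataDefinition = StrataDefinition(),
    seed: int = 0,
) -> FoldPlan:
    """Stratified k-fold assignments, repeated with fresh shuffles.

    Observations are dealt round-robin to folds in stratum order (event
    strata first, shuffled within stratum, continuing the fold counter
    across strata from a random offset).  Consequences: fold sizes within
    each stratum differ by at most one, overall fold sizes are balanced,
    and whenever the input holds at least k events every fold receives one.
    """
    time = np.asarray(time, float)
    n = len(time)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of observations n = {n}")
    status = np.asarray(status)
    if status.dtype.kind in "OU":
        status = status == "deceased"
    labels = build_strata(time, status, group, strata)
    assignment = np.empty((repeats, n), dtype=int)
    rng = np.random.default_rng(seed)
    for r in range(repeats):
        order = _ordered_deal(labels, status, rng)
        start = int(rng.integers(k))
        assignment[r, order] = (start + np.arange(n)) % k
    return FoldPlan(k=k, repeats=repeats, assignment=assignment, seed=seed)
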