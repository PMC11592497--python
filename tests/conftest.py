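"""Shared fixtures: default synthetic cohort and derived modeling objects.

Expensive objects are session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chdsurv import preprocessing as prep
from chdsurv import synthetic as syn
from chdsurv import partitioning as part


@pytest.fixture(scope="session")
def default_spec():
    return syn.default_spec(seed=0)


@pytest.fixture(scope="session")
def raw_cohort(default_spec):
    raw = syn.generate_cohort(default_spec)
    return syn.inject_missingness(raw, default_spec.missingness_rates, seed=1)


@pytest.fixture(scope="session")
def engineered(raw_cohort):
    imputed = prep.impute_chained(raw_cohort, n_iterations=10, seed=2)
    eng = prep.engineer_features(imputed)
    eng, _, _, _ = prep.censor_followup_outliers(eng)
    return eng


@pytest.fixture(scope="session")
def design(engineered):
    """(X, time, event, group) for the default cohort."""
    X = prep.encode_design_matrix(engineered)
    t, e = prep.survival_arrays(engineered)
    return X, t, e, engineered["disease_group"].to_numpy()


@pytest.fixture(scope="session")
def split_ids(design):
    X, t, e, g = design
    return part.stratified_partition(t, e, g, ratio=0.6, seed=3)


def simulate_cox_data(n, beta, seed, censor_rate=2.0):
    """Independent-covariate Cox data with exponential baseline hazard 1."""
    rng = np.random.default_rng(seed)
    p = len(beta)
    X = rng.normal(size=(n, p))
    lp = X @ np.asarray(beta)
    t_death = rng.exponential(1.0, n) / np.exp(lp)
    t_cens = rng.exponential(censor_rate, n)
    time = np.minimum(t_death, t_cens)
    event = t_death <= t_cens
    Xdf = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
    return Xdf, time, event, lp
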