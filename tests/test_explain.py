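"""Shapley engine: additivity, closed-form oracles, aggregation arithmetic,
time-dependent curves, rankings."""

import numpy as np
import pandas as pd
import pytest

from chdsurv import explain as ex
from chdsurv import models as mod
from chdsurv.models import RiskModel
from conftest import simulate_cox_data


def _fn_model(f, p, capabilities=("risk",), surv=None):
    """Wrap a plain function as a RiskModel for engine testing."""
    return RiskModel(
        kind="test",
        capabilities=frozenset(capabilities),
        _predict_risk=f,
        _predict_survival=surv,
        feature_names=tuple(f"x{j}" for j in range(p)),
    )


# --------------------------------------------------------------------------
# exact estimator
# --------------------------------------------------------------------------


def test_exact_additive_model_closed_form():
    """f(x) = sum_j g_j(x_j): exact attributions equal
    g_j(x_j) - mean over background of g_j."""
    rng = np.random.default_rng(0)
    gs = [lambda v: v, lambda v: v**2, lambda v: np.sin(v)]

    def f(M):
        return sum(g(M[:, j]) for j, g in enumerate(gs))

    X = rng.normal(size=(12, 3))
    bg = rng.normal(size=(40, 3))
    model = _fn_model(f, 3)
    sm = ex.shap_attributions(model, X, bg, method="exact")
    for j, g in enumerate(gs):
        expected = g(X[:, j]) - g(bg[:, j]).mean()
        assert np.allclose(sm.values[:, j], expected, atol=1e-9)
    assert np.allclose(sm.base + sm.values.sum(1), f(X), atol=1e-9)


def test_exact_ignored_feature_gets_zero():
    def f(M):
        return M[:, 0] * 2.0  # feature 1 provably ignored

    rng = np.random.default_rng(1)
    model = _fn_model(f, 2)
    sm = ex.shap_attributions(model, rng.normal(size=(8, 2)), rng.normal(size=(16, 2)), method="exact")
    assert np.allclose(sm.values[:, 1], 0.0, atol=1e-12)


def test_exact_rejects_large_p():
    model = _fn_model(lambda M: M.sum(1), 12)
    X = np.zeros((2, 12))
    with pytest.raises(ValueError, match="sampling"):
        ex.shap_attributions(model, X, X, method="exact")


def test_empty_background_rejected():
    model = _fn_model(lambda M: M.sum(1), 2)
    with pytest.raises(ValueError, match="non-empty"):
        ex.shap_attributions(model, np.zeros((2, 2)), np.zeros((0, 2)))


# --------------------------------------------------------------------------
# sampling estimator vs exact enumeration
# --------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fitted_p6():
    """A fitted boosted-Cox model on p = 6 with interactions."""
    X, t, e, _ = simulate_cox_data(500, beta=[1.0, -0.8, 0.5, 0.0, 0.3, -0.2], seed=2)
    cfg = mod.BoostedCoxConfig(num_rounds=80, early_stopping_rounds=None, max_depth=3)
    return mod.fit_boosted_cox(X, t, e, config=cfg, seed=0), X


def test_sampling_additivity_exact_by_telescoping(fitted_p6):
    model, X = fitted_p6
    sm = ex.shap_attributions(model, X.iloc[:40], X, method="sampling", seed=3, n_permutations=8)
    assert np.allclose(sm.base + sm.values.sum(1), sm.predictions, atol=1e-9)


def test_sampling_close_to_exact_enumeration(fitted_p6):
    """On a p = 6 fit the sampling estimator reproduces exact enumeration
    within its own reported Monte-Carlo tolerance, and the error shrinks
    with the permutation budget."""
    model, X = fitted_p6
    bg = X.iloc[:48]
    exact = ex.shap_attributions(model, X.iloc[:24], bg, method="exact", max_background=None)
    sampled = ex.shap_attributions(
        model, X.iloc[:24], bg, method="sampling", seed=4, n_permutations=256, max_background=None
    )
    dev = np.abs(sampled.values - exact.values)
    # elementwise: within 6 reported standard errors (plus a tiny floor)
    assert (dev <= 6.0 * sampled.mc_se + 1e-9).all()
    # and the average deviation is small relative to the attribution scale
    assert dev.mean() < 0.05 * np.abs(exact.values).max()
    coarse = ex.shap_attributions(
        model, X.iloc[:24], bg, method="sampling", seed=4, n_permutations=16, max_background=None
    )
    assert np.abs(coarse.values - exact.values).mean() > dev.mean()


def test_tree_estimator_matches_exact_for_boosted_cox(fitted_p6):
    """xgboost's native tree attribution agrees with interventional exact
    enumeration on rankings and satisfies additivity exactly."""
    model, X = fitted_p6
    sm = ex.shap_attributions(model, X.iloc[:64], X, method="tree")
    assert np.allclose(sm.base + sm.values.sum(1), sm.predictions, atol=1e-4)
    exact = ex.shap_attributions(model, X.iloc[:64], X.iloc[:48], method="exact", max_background=None)
    # top feature agrees between the two estimators
    assert sm.mean_abs().idxmax() == exact.mean_abs().idxmax()


def test_tree_method_rejected_for_non_boosted_models():
    model = _fn_model(lambda M: M.sum(1), 2)
    with pytest.raises(ValueError, match="boosted_cox"):
        ex.shap_attributions(model, np.zeros((2, 2)), np.ones((3, 2)), method="tree")


# --------------------------------------------------------------------------
# aggregation arithmetic
# --------------------------------------------------------------------------


def _random_matrices(l, n=7, p=4, seed=0):
    rng = np.random.default_rng(seed)
    names = tuple(f"x{j}" for j in range(p))
    return [
        ex.ShapMatrix(values=rng.normal(size=(n, p)), base=rng.normal(size=n),
                      feature_names=names, model_id=f"m{k}")
        for k in range(l)
    ]


def test_aggregate_single_matrix_identity():
    (m,) = _random_matrices(1)
    agg = ex.aggregate_shap_over_models([m])
    assert np.array_equal(agg.values, m.values)
    assert agg.n_models == 1


def test_aggregate_equals_elementwise_mean():
    mats = _random_matrices(3, seed=5)
    agg = ex.aggregate_shap_over_models(mats)
    direct = np.mean([m.values for m in mats], axis=0)
    assert np.allclose(agg.values, direct, atol=1e-12)


def test_aggregate_shape_mismatch_errors():
    a, b = _random_matrices(2)
    b.values = b.values[:, :2]
    b.feature_names = b.feature_names[:2]
    with pytest.raises(ValueError, match="match"):
        ex.aggregate_shap_over_models([a, b])


def test_aggregation_linearity_consistency():
    """mean over models of (base_k + sum_j phi_k) equals the aggregate's
    base plus sum of aggregated attributions, observation by observation."""
    mats = _random_matrices(5, seed=6)
    agg = ex.aggregate_shap_over_models(mats)
    lhs = np.mean([m.base + m.values.sum(1) for m in mats], axis=0)
    rhs = agg.base + agg.values.sum(1)
    assert np.allclose(lhs, rhs, atol=1e-12)


# --------------------------------------------------------------------------
# time-dependent curves
# --------------------------------------------------------------------------


def _cph_two_feature():
    """CPH with beta = (1, -1) fitted on matching simulated data."""
    X, t, e, _ = simulate_cox_data(800, beta=[1.0, -1.0], seed=7)
    return mod.fit_cph(X, t, e), X, t, e


def test_survshap_requires_survival_capability():
    X, t, e, _ = simulate_cox_data(200, beta=[1.0], seed=8)
    m = mod.fit_boosted_cox(
        X, t, e, config=mod.BoostedCoxConfig(num_rounds=5, early_stopping_rounds=None), seed=0
    )
    with pytest.raises(ValueError, match="survival"):
        ex.survshap_curves(m, X.iloc[:3], X, np.array([1.0]))


def test_survshap_cph_signs_and_additivity():
    """Two-feature CPH, beta = (1, -1): exact per-time additivity holds to
    1e-6, and curve signs track the coefficient signs for feature values
    above the background mean."""
    m, X, t, e = _cph_two_feature()
    grid = np.quantile(t[e], [0.2, 0.4, 0.6, 0.8])
    bg = X.iloc[:100]
    probe = pd.DataFrame({"x0": [2.0, -2.0], "x1": [2.0, -2.0]})
    curves = ex.survshap_curves(m, probe, bg, grid, method="exact", max_background=None)
    S = m.predict_survival(probe, grid)
    Sbar = m.predict_survival(bg, grid).mean(axis=0)
    total = curves.values.sum(axis=1)
    assert np.allclose(total, S - curves.base, atol=1e-6)
    assert np.allclose(curves.base, Sbar, atol=1e-6)
    # high x0 (beta +1) lowers survival; high x1 (beta -1) raises it
    assert (curves.values[0, 0, :] < 0).all()
    assert (curves.values[0, 1, :] > 0).all()
    # and mirrored for the low-value probe
    assert (curves.values[1, 0, :] > 0).all()
    assert (curves.values[1, 1, :] < 0).all()


def test_survshap_feature_ignoring_model_zero_curves():
    grid = np.array([1.0, 2.0])

    def surv(M, times):
        return np.full((len(M), len(times)), 0.7)

    m = RiskModel(kind="test", capabilities=frozenset({"risk", "survival_function"}),
                  _predict_risk=lambda M: np.zeros(len(M)), _predict_survival=surv,
                  feature_names=("x0", "x1"))
    curves = ex.survshap_curves(m, np.zeros((4, 2)), np.ones((8, 2)), grid, method="exact")
    assert np.allclose(curves.values, 0.0, atol=1e-12)


def test_survshap_constant_beyond_last_event():
    m, X, t, e = _cph_two_feature()
    t_max = t[e].max()
    grid = np.array([t_max, t_max * 2, t_max * 10])
    curves = ex.survshap_curves(m, X.iloc[:5], X.iloc[:50], grid, method="exact", max_background=None)
    assert np.allclose(curves.values[:, :, 0], curves.values[:, :, 1], atol=1e-12)
    assert np.allclose(curves.values[:, :, 0], curves.values[:, :, 2], atol=1e-12)


def test_global_survshap_is_mean_over_observations():
    rng = np.random.default_rng(9)
    curves = ex.SurvShapCurves(
        values=rng.normal(size=(6, 3, 4)), base=rng.normal(size=(6, 4)),
        grid=np.arange(4.0), feature_names=("a", "b", "c"),
    )
    g = ex.global_survshap(curves)
    direct = curves.values.mean(axis=0)
    for j, feat in enumerate(curves.feature_names):
        got = g[g["feature"] == feat].sort_values("t")["value"].to_numpy()
        assert np.allclose(got, direct[j], atol=1e-12)


def test_global_survshap_single_observation_identity():
    rng = np.random.default_rng(10)
    curves = ex.SurvShapCurves(
        values=rng.normal(size=(1, 2, 3)), base=rng.normal(size=(1, 3)),
        grid=np.arange(3.0), feature_names=("a", "b"),
    )
    g = ex.global_survshap(curves)
    assert np.allclose(
        g[g["feature"] == "a"]["value"], curves.values[0, 0], atol=1e-12
    )


def test_aggregate_survshap_mean_and_identity():
    rng = np.random.default_rng(11)
    def mk():
        rows = []
        for f in ("a", "b"):
            for t in (1.0, 2.0):
                rows.append({"feature": f, "t": t, "value": rng.normal()})
        return pd.DataFrame(rows)

    gs = [mk() for _ in range(5)]
    agg = ex.aggregate_survshap_over_models(gs)
    direct = np.mean([g["value"].to_numpy() for g in gs], axis=0)
    assert np.allclose(agg["value"], direct, atol=1e-12)
    one = ex.aggregate_survshap_over_models([gs[0]])
    assert np.allclose(one["value"], gs[0]["value"], atol=1e-12)
    zero = gs[0].assign(value=0.0)
    assert (ex.aggregate_survshap_over_models([zero, zero])["value"] == 0).all()


# --------------------------------------------------------------------------
# rankings and group summaries
# --------------------------------------------------------------------------


def test_ranking_ties_broken_lexicographically():
    mean_abs = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
    ranks = ex.mean_abs_ranking(mean_abs)
    assert ranks["c"] == 1 and ranks["a"] == 2 and ranks["b"] == 3


def test_top_k_rank_frequency_hand_oracle():
    t1 = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0, "d": 0.5})
    t2 = pd.Series({"a": 0.1, "b": 2.0, "c": 1.0, "d": 0.5})
    t3 = pd.Series({"a": 3.0, "b": 0.1, "c": 1.0, "d": 2.0})
    counts = ex.top_k_rank_frequency([t1, t2, t3], k=2)
    assert counts["a"] == 2  # top-2 in t1, t3
    assert counts["b"] == 2  # t1, t2
    assert counts["c"] == 1  # t2
    assert counts["d"] == 1  # t3


def test_top_k_single_model_indicator():
    t1 = pd.Series({"a": 3.0, "b": 2.0, "c": 1.0})
    counts = ex.top_k_rank_frequency([t1], k=1)
    assert counts["a"] == 1 and counts["b"] == 0 and counts["c"] == 0


def test_group_force_summary_matches_groupby():
    rng = np.random.default_rng(12)
    agg = ex.AggregatedShap(values=rng.normal(size=(20, 3)), base=np.zeros(20),
                            feature_names=("a", "b", "c"), n_models=1)
    groups = np.array(["G1"] * 12 + ["G2"] * 8)
    out = ex.group_force_summary(agg, groups)
    df = pd.DataFrame(agg.values, columns=["a", "b", "c"]).assign(g=groups)
    expect = df.groupby("g").mean()
    for _, row in out.iterrows():
        assert row["mean_phi"] == pytest.approx(expect.loc[row["group"], row["feature"]], abs=1e-12)


def test_group_force_mirrored_groups_opposite_signs():
    values = np.vstack([np.ones((5, 2)), -np.ones((5, 2))])
    agg = ex.AggregatedShap(values=values, base=np.zeros(10), feature_names=("a", "b"), n_models=1)
    out = ex.group_force_summary(agg, np.array(["P"] * 5 + ["N"] * 5))
    p = out[out["group"] == "P"]["mean_phi"].to_numpy()
    n = out[out["group"] == "N"]["mean_phi"].to_numpy()
    assert np.allclose(p, -n)


def test_union_of_top5_tables_reproduces_reference_feature_set():
    """Two published-style mean-|SHAP| tables (one per ML family) produce a
    7-feature union of their top-5 sets: age at surgery, aortic cross clamp
    time, days between admission and surgery, disease group, open thorax,
    creatinine max, urea max."""
    xgb = pd.Series({
        "creatinine_max": 0.38, "disease_group": 0.20, "urea_max": 0.15,
        "open_thorax": 0.13, "age_at_surgery": 0.12, "crp_max": 0.05,
        "aortic_cross_clamp_time": 0.04, "days_admission_to_surgery": 0.03,
    })
    rsf = pd.Series({
        "creatinine_max": 0.31, "days_admission_to_surgery": 0.24,
        "aortic_cross_clamp_time": 0.19, "disease_group": 0.19,
        "age_at_surgery": 0.18, "urea_max": 0.10, "open_thorax": 0.08,
        "crp_max": 0.02,
    })
    union = set()
    for table in (xgb, rsf):
        ranks = ex.mean_abs_ranking(table)
        union |= set(ranks[ranks <= 5].index)
    assert union == {
        "age_at_surgery", "aortic_cross_clamp_time", "days_admission_to_surgery",
        "disease_group", "open_thorax", "creatinine_max", "urea_max",
    }


def test_group_force_unknown_label_errors():
    agg = ex.AggregatedShap(values=np.zeros((2, 1)), base=np.zeros(2),
                            feature_names=("a",), n_models=1)
    with pytest.raises(ValueError, match="unknown group"):
        ex.group_force_summary(agg, np.array(["X", "Y"]), valid_groups=["X"])
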