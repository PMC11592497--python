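"""End-to-end orchestration: simulate → preprocess → split → tune →
validate → explain → CPH comparison → report.

Every stage writes its artifacts (CSV/JSON) into the run directory and the
manifest records paths, seeds, status and a hash of the configuration, so a
run is reproducible bit-for-bit from ``(config, master seed)``.  Stage
seeds are derived deterministically from the master seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import explain as ex
from . import hpo
from . import models as mod
from . import partitioning as part
from . import preprocessing as prep
from . import synthetic as syn
from .evaluation import harrell_c_index, summarize_risk_sets

__all__ = ["PipelineConfig", "run_end_to_end"]

_FAMILIES = ("rsf", "boosted_cox")


@dataclass
class ExplainSettings:
    n_permutations: int = 64
    max_explain_obs: int | None = None  # None: all holdout observations
    max_background: int = 64
    survshap_n_models: int = 100
    survshap_n_obs: int = 128
    survshap_n_permutations: int = 8
    survshap_grid_points: int = 40
    top_k: int = 5


@dataclass
class PipelineConfig:
    """Everything a run needs.  ``profile='reduced'`` shrinks the tuning
    budget and the attribution sampling effort to desk scale; the CV layout
    (10×10) and the cohort itself are unchanged."""

    cohort_csv: str | None = None  # if given, skip simulation
    split_ratio: float = 0.6
    cv_k: int = 10
    cv_repeats: int = 10
    hpo_profile: str = "full"  # {"full", "reduced"}
    #: optional overrides of the tuning budget (n_init / n_iterations /
    #: n_sampling_runs), e.g. for smoke-scale runs
    hpo_budget: dict | None = None
    model_families: tuple = _FAMILIES
    explain: ExplainSettings = field(default_factory=ExplainSettings)
    outlier_quantile: float = 0.995
    outdir: str = "chdsurv_run"
    seed: int = 0

    @classmethod
    def reduced(cls, outdir: str = "chdsurv_run", seed: int = 0) -> "PipelineConfig":
        return cls(
            hpo_profile="reduced",
            explain=ExplainSettings(
                n_permutations=8,
                max_explain_obs=128,
                survshap_n_models=10,
                survshap_n_obs=64,
                survshap_n_permutations=4,
            ),
            outdir=outdir,
            seed=seed,
        )

    def validate(self) -> None:
        for f_ in self.model_families:
            if f_ not in _FAMILIES:
                raise ValueError(f"unknown model family {f_!r}; choose from {_FAMILIES}")
        if self.hpo_profile not in ("full", "reduced"):
            raise ValueError(f"hpo_profile must be 'full' or 'reduced', got {self.hpo_profile!r}")
        if not (0 < self.split_ratio < 1):
            raise ValueError("split_ratio must lie in (0, 1)")
        if self.cohort_csv is not None and not Path(self.cohort_csv).exists():
            raise ValueError(f"cohort_csv path does not exist: {self.cohort_csv}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_families"] = list(self.model_families)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage_seed(master: int, offset: int) -> int:
    return (int(master) * 1009 + offset) % (2**31 - 1)


def run_end_to_end(config: PipelineConfig) -> dict:
    """Run the full workflow; returns (and writes) the run manifest."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "stages": {},
    }
    state: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("preprocess", _stage_preprocess),
        ("split", _stage_split),
        ("tune", _stage_tune),
        ("validate", _stage_validate),
        ("explain", _stage_explain),
        ("cph", _stage_cph),
        ("report", _stage_report),
    ]
    failed = False
    for name, fn in stages:
        rec: dict = {"status": "skipped"}
        manifest["stages"][name] = rec
        if failed:
            continue
        t0 = time.time()
        try:
            artifacts = fn(config, state, out)
            rec.update(status="ok", artifacts=artifacts, wall_time_s=round(time.time() - t0, 2))
        except Exception as exc:  # noqa: BLE001 — manifest must record the failure
            rec.update(status="failed", error=f"{type(exc).__name__}: {exc}")
            failed = True
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _stage_simulate(config: PipelineConfig, state: dict, out: Path) -> dict:
    if config.cohort_csv is not None:
        state["raw"] = syn.read_cohort_csv(config.cohort_csv)
        return {"cohort": config.cohort_csv, "source": "external"}
    spec = syn.default_spec(_stage_seed(config.seed, 1))
    raw = syn.generate_cohort(spec)
    raw = syn.inject_missingness(raw, spec.missingness_rates, _stage_seed(config.seed, 2))
    path = out / "cohort_raw.csv"
    syn.write_cohort_csv(raw, path)
    (out / "cohort_spec.json").write_text(json.dumps(syn.spec_to_dict(spec), indent=2))
    state["raw"] = raw
    return {"cohort": str(path), "spec": str(out / "cohort_spec.json")}


def _stage_preprocess(config: PipelineConfig, state: dict, out: Path) -> dict:
    imputed = prep.impute_chained(state["raw"], n_iterations=10, seed=_stage_seed(config.seed, 3))
    eng = prep.engineer_features(imputed)
    eng, n_aff, n_ev, thr = prep.censor_followup_outliers(eng, config.outlier_quantile)
    report = prep.prune_correlated(eng)
    summary = prep.cohort_summary(eng)
    eng.to_csv(out / "engineered.csv", index=False)
    report.to_csv(out / "correlation_report.csv", index=False)
    summary.groups.to_csv(out / "summary_groups.csv")
    (out / "summary.json").write_text(json.dumps(summary.to_json_dict(), indent=2))
    state["eng"] = eng
    state["X"] = prep.encode_design_matrix(eng)
    state["time"], state["event"] = prep.survival_arrays(eng)
    state["group"] = eng["disease_group"].to_numpy()
    return {
        "engineered": str(out / "engineered.csv"),
        "outlier_censoring": {"n_affected": n_aff, "n_events_affected": n_ev, "threshold_days": thr},
        "correlation_report": str(out / "correlation_report.csv"),
        "summary": str(out / "summary.json"),
    }


def _stage_split(config: PipelineConfig, state: dict, out: Path) -> dict:
    t, e, g = state["time"], state["event"], state["group"]
    tr, te = part.stratified_partition(
        t, e, g, config.split_ratio, seed=_stage_seed(config.seed, 4)
    )
    plan = part.repeated_cv_folds(
        t[tr], e[tr], g[tr], k=config.cv_k, repeats=config.cv_repeats,
        seed=_stage_seed(config.seed, 5),
    )
    tune_folds = part.repeated_cv_folds(
        t[tr], e[tr], g[tr], k=3, repeats=1, seed=_stage_seed(config.seed, 6)
    )
    pd.DataFrame({"observation": np.concatenate([tr, te]),
                  "partition": ["train"] * len(tr) + ["test"] * len(te)}
                 ).to_csv(out / "partition.csv", index=False)
    plan.to_frame().to_csv(out / "fold_plan.csv", index=False)
    state.update(train_ids=tr, test_ids=te, plan=plan, tune_folds=tune_folds)
    return {"partition": str(out / "partition.csv"), "fold_plan": str(out / "fold_plan.csv"),
            "n_train": int(len(tr)), "n_test": int(len(te))}


def _cv_objective(family: str, state: dict, config: PipelineConfig):
    """Mean stratified 3-fold CV C-index of a hyperparameter setting."""
    tr = state["train_ids"]
    X, t, e = state["X"].iloc[tr], state["time"][tr], state["event"][tr]
    folds = state["tune_folds"]
    seed = _stage_seed(config.seed, 7)

    def objective(setting: dict) -> float:
        cs = []
        for r, f_ in folds.tasks():
            itr, ite = folds.train_indices(r, f_), folds.test_indices(r, f_)
            if family == "rsf":
                m = mod.fit_rsf(
                    X.iloc[itr], t[itr], e[itr],
                    mod.RSFConfig(
                        num_trees=setting["num_trees"], max_depth=setting["max_depth"],
                        mtry=setting["mtry"], min_node_size=setting["min_node_size"],
                        sample_fraction=setting["sample_fraction"],
                    ),
                    seed=seed,
                )
            else:
                m = mod.fit_boosted_cox(
                    X.iloc[itr], t[itr], e[itr],
                    mod.BoostedCoxConfig(
                        max_depth=setting["max_depth"], learning_rate=setting["learning_rate"],
                        subsample=setting["subsample"], colsample_bytree=setting["colsample_bytree"],
                        min_child_weight=setting["min_child_weight"],
                    ),
                    validation=(X.iloc[ite], t[ite], e[ite]),
                    seed=seed,
                )
            cs.append(harrell_c_index(t[ite], e[ite], m.predict_risk(X.iloc[ite])))
        return float(np.mean(cs))

    return objective


def _stage_tune(config: PipelineConfig, state: dict, out: Path) -> dict:
    budget = dict(hpo.REDUCED_BAYESOPT) if config.hpo_profile == "reduced" else {}
    if config.hpo_budget:
        budget.update(config.hpo_budget)
    artifacts = {}
    state["best"] = {}
    for family in config.model_families:
        space = hpo.rsf_search_space() if family == "rsf" else hpo.boosted_cox_search_space()
        cfg = hpo.BayesOptConfig(seed=_stage_seed(config.seed, 8), **budget)
        result = hpo.bayesian_optimize(_cv_objective(family, state, config), space, cfg)
        result.trace.to_csv(out / f"tuning_trace_{family}.csv", index=False)
        (out / f"best_setting_{family}.json").write_text(json.dumps(result.to_json_dict(), indent=2))
        state["best"][family] = result.best_setting
        artifacts[family] = {"trace": str(out / f"tuning_trace_{family}.csv"),
                             "best": result.best_setting, "best_cv_c_index": result.best_value}
    return artifacts


def _iter_cv_models(family: str, state: dict, config: PipelineConfig):
    """Yield fitted CV models one at a time (memory: a forest's node-level
    survival arrays are large, so models are consumed and discarded)."""
    tr = state["train_ids"]
    X, t, e = state["X"].iloc[tr], state["time"][tr], state["event"][tr]
    plan = state["plan"]
    best = state["best"][family]
    for r, f_ in plan.tasks():
        itr, ite = plan.train_indices(r, f_), plan.test_indices(r, f_)
        seed = _stage_seed(config.seed, 100 + 10 * r + f_)
        if family == "rsf":
            m = mod.fit_rsf(
                X.iloc[itr], t[itr], e[itr],
                mod.RSFConfig(
                    num_trees=best["num_trees"], max_depth=best["max_depth"], mtry=best["mtry"],
                    min_node_size=best["min_node_size"], sample_fraction=best["sample_fraction"],
                ),
                seed=seed,
            )
        else:
            m = mod.fit_boosted_cox(
                X.iloc[itr], t[itr], e[itr],
                mod.BoostedCoxConfig(
                    max_depth=best["max_depth"], learning_rate=best["learning_rate"],
                    subsample=best["subsample"], colsample_bytree=best["colsample_bytree"],
                    min_child_weight=best["min_child_weight"],
                ),
                validation=(X.iloc[ite], t[ite], e[ite]),
                seed=seed,
            )
        m.metadata["cv_task"] = (r, f_)
        m.metadata["train_indices"] = itr
        yield m


def _explain_subset(config: PipelineConfig, state: dict) -> np.ndarray:
    te = state["test_ids"]
    es = config.explain
    rng = np.random.default_rng(_stage_seed(config.seed, 9))
    if es.max_explain_obs is not None and len(te) > es.max_explain_obs:
        return np.sort(rng.choice(len(te), size=es.max_explain_obs, replace=False))
    return np.arange(len(te))


def _stage_validate(config: PipelineConfig, state: dict, out: Path) -> dict:
    """One streaming pass per family: fit each CV model, score it on its
    validation fold and on the holdout, compute its attributions, discard it."""
    es = config.explain
    tr, te = state["train_ids"], state["test_ids"]
    plan = state["plan"]
    Xtr, ttr, etr = state["X"].iloc[tr], state["time"][tr], state["event"][tr]
    Xte = state["X"].iloc[te]
    sub = _explain_subset(config, state)
    Xex = Xte.iloc[sub]
    state["explain_sub"] = sub
    grid = ex.default_time_grid(ttr, etr, max_points=es.survshap_grid_points)

    records = []
    state["holdout_risks"] = {}
    state["shap_mats"] = {}
    state["survshap_globals"] = []
    for family in config.model_families:
        risks, mats = [], []
        for k, m in enumerate(_iter_cv_models(family, state, config)):
            r, f_ = m.metadata["cv_task"]
            ite = plan.test_indices(r, f_)
            c_val = harrell_c_index(ttr[ite], etr[ite], m.predict_risk(Xtr.iloc[ite]))
            rec = {"family": family, "repeat": r, "fold": f_, "validation_c_index": c_val}
            if family == "boosted_cox":
                rec["n_rounds"] = m.metadata["n_rounds"]
            records.append(rec)
            risks.append(m.predict_risk(Xte))
            bg = Xtr.iloc[m.metadata["train_indices"]]
            method = "tree" if family == "boosted_cox" else "sampling"
            mats.append(ex.shap_attributions(
                m, Xex, bg, method=method,
                seed=_stage_seed(config.seed, 500 + k),
                n_permutations=es.n_permutations, max_background=es.max_background,
                model_id=f"{family}_{k:03d}",
            ))
            if family == "rsf" and k < es.survshap_n_models:
                n_obs = min(es.survshap_n_obs, len(Xex))
                curves = ex.survshap_curves(
                    m, Xex.iloc[:n_obs], bg, grid, method="sampling",
                    seed=_stage_seed(config.seed, 900 + k),
                    n_permutations=es.survshap_n_permutations,
                    max_background=es.max_background, model_id=f"rsf_{k:03d}",
                )
                state["survshap_globals"].append(ex.global_survshap(curves))
            del m
        state["holdout_risks"][family] = np.array(risks)
        state["shap_mats"][family] = mats
    df = pd.DataFrame(records)
    df.to_csv(out / "validation_c_index.csv", index=False)
    return {"validation": str(out / "validation_c_index.csv"),
            "n_models": {f_: int(len(state["holdout_risks"][f_])) for f_ in config.model_families}}


def _stage_explain(config: PipelineConfig, state: dict, out: Path) -> dict:
    """Aggregate the per-model attributions of the validation pass."""
    es = config.explain
    te = state["test_ids"]
    sub = state["explain_sub"]
    groups_ex = state["group"][te][sub]

    artifacts: dict = {}
    state["agg_shap"] = {}
    for family in config.model_families:
        mats = state["shap_mats"][family]
        tables = [m.mean_abs() for m in mats]
        agg = ex.aggregate_shap_over_models(mats)
        state["agg_shap"][family] = agg
        agg_df = pd.DataFrame(agg.values, columns=list(agg.feature_names))
        agg_df.insert(0, "observation", te[sub])
        agg_df.to_csv(out / f"shap_aggregated_{family}.csv", index=False)
        agg.mean_abs().rename("mean_abs_shap").to_csv(out / f"shap_mean_abs_{family}.csv")
        freq = ex.top_k_rank_frequency(tables, k=es.top_k)
        freq.rename("n_models_top_k").to_csv(out / f"rank_frequency_{family}.csv")
        rank1 = ex.top_k_rank_frequency(tables, k=1)
        rank1.rename("n_models_rank1").to_csv(out / f"rank1_frequency_{family}.csv")
        force = ex.group_force_summary(agg, groups_ex, valid_groups=syn.DISEASE_GROUPS)
        force.to_csv(out / f"group_force_{family}.csv", index=False)
        artifacts[family] = {
            "aggregated_shap": str(out / f"shap_aggregated_{family}.csv"),
            "mean_abs": str(out / f"shap_mean_abs_{family}.csv"),
            "rank_frequency": str(out / f"rank_frequency_{family}.csv"),
            "group_force": str(out / f"group_force_{family}.csv"),
            "top_ranking": list(agg.ranking().index[: es.top_k]),
        }

    if state["survshap_globals"]:
        agg_curves = ex.aggregate_survshap_over_models(state["survshap_globals"])
        agg_curves.to_csv(out / "survshap_global_aggregated.csv", index=False)
        artifacts["survshap"] = {
            "aggregated_global_curves": str(out / "survshap_global_aggregated.csv"),
            "n_models": len(state["survshap_globals"]),
        }
    return artifacts


def _stage_cph(config: PipelineConfig, state: dict, out: Path) -> dict:
    """CPH on the union of the two families' top-5 features, same CV setup."""
    union: set = set()
    for family in config.model_families:
        union |= set(state["agg_shap"][family].ranking().index[: config.explain.top_k])
    features = sorted(union)
    tr, te = state["train_ids"], state["test_ids"]
    X, t, e = state["X"].iloc[tr], state["time"][tr], state["event"][tr]
    Xte = state["X"].iloc[te]
    plan = state["plan"]
    risks = []
    for r, f_ in plan.tasks():
        itr = plan.train_indices(r, f_)
        m = mod.fit_cph(X.iloc[itr], t[itr], e[itr], features=features, alpha=0.01)
        risks.append(m.predict_risk(Xte))
    state["holdout_risks"]["cph"] = np.array(risks)
    full = mod.fit_cph(X, t, e, features=features, alpha=0.01)
    (out / "cph_features.json").write_text(json.dumps(
        {"union_features": features, "full_model_coef": full.metadata["coef"]}, indent=2))
    return {"union_features": features, "n_models": len(risks),
            "full_model": str(out / "cph_features.json")}


def _stage_report(config: PipelineConfig, state: dict, out: Path) -> dict:
    te = state["test_ids"]
    perf = summarize_risk_sets(
        state["holdout_risks"], state["time"][te], state["event"][te],
        groups=state["group"][te],
    )
    perf.per_model.to_csv(out / "holdout_c_index_per_model.csv", index=False)
    perf.summary.to_csv(out / "performance_summary.csv", index=False)
    (out / "performance_summary.json").write_text(
        perf.summary.to_json(orient="records", indent=2)
    )
    state["performance"] = perf
    return {
        "per_model": str(out / "holdout_c_index_per_model.csv"),
        "summary": str(out / "performance_summary.csv"),
        "holdout_mean_c_index": {
            f_: perf.mean_c(f_) for f_ in list(config.model_families) + ["cph"]
            if (perf.summary["family"] == f_).any()
        },
    }
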