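"""Synthetic cohort generator for a pediatric heart-surgery survival study.

The generator emulates a monocentric cohort of children undergoing surgery
for congenital heart disease (CHD).  Patients fall into four disease groups
of decreasing severity — ``UVHD I`` (univentricular, palliation stage I),
``UVHD II`` (stage II/III), ``BVHD cmplx.`` and ``BVHD smpl.`` (complex and
simple biventricular disease) — with group sizes 50/111/291/850 and strongly
group-dependent in-hospital mortality (roughly 62 %, 7.2 %, 9.6 % and
0.7 %).

The survival mechanism is a latent competing pair of durations measured in
days from surgery:

* a death time drawn from a Weibull law with a shared shape and a
  group-specific scale, accelerated by ``exp(eta)`` where ``eta`` is a
  linear predictor over (internally standardized) covariates, and
* a discharge time drawn from a group-specific lognormal law.

The observed follow-up is the minimum of the two; discharge acts as
censoring.  A handful of covariates carry planted log-hazard effects
(strongest on the post-surgery creatinine maximum) so that downstream
feature-importance machinery has a known ground truth to recover.

Covariate marginals (ages, weights, lab levels, surgery descriptors) are
loosely matched to the cohort summaries such a registry would publish; the
generator makes no attempt at physiological realism beyond that.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DISEASE_GROUPS",
    "HISTORY_GROUPS",
    "CohortSpec",
    "default_spec",
    "generate_cohort",
    "inject_missingness",
    "write_cohort_csv",
    "read_cohort_csv",
]

#: Disease groups in the column order used throughout the package.
DISEASE_GROUPS = ("UVHD I", "UVHD II", "BVHD cmplx.", "BVHD smpl.")

#: Historical (previous-hospitalization) group labels, decreasing severity.
HISTORY_GROUPS = ("UVHD Ia", "UVHD Ib", "BVHD cmplx.", "UVHD II/III", "BVHD smpl.")

LAB_ANALYTES = ("creatinine", "urea", "crp", "leukocytes")

# Per-group covariate distribution parameters, indexed like DISEASE_GROUPS.
_GROUP_PARAMS = {
    "p_male": (0.60, 0.658, 0.643, 0.519),
    # median age at admission in days and lognormal sigma
    "age_median": (0.5, 1097.0, 20.0, 169.0),
    "age_sigma": (2.0, 1.0, 2.2, 1.0),
    # weight in grams (lognormal median / sigma)
    "weight_median": (3300.0, 13000.0, 3960.0, 6900.0),
    "weight_sigma": (0.15, 0.45, 0.35, 0.40),
    "height_median": (51.5, 92.0, 54.0, 65.0),
    "height_sigma": (0.08, 0.20, 0.18, 0.18),
    "days_adm_surg_median": (6.0, 1.0, 3.0, 1.0),
    "days_adm_surg_sigma": (0.8, 0.3, 1.0, 0.3),
    "prev_adm_lambda": (0.30, 1.80, 0.50, 0.12),
    "p_malformations": (0.32, 0.198, 0.134, 0.104),
    "p_chrom_alterations": (0.06, 0.018, 0.089, 0.212),
    "p_pulm_hypertension": (0.005, 0.018, 0.014, 0.011),
    "p_circulatory_arrest": (0.50, 0.10, 0.25, 0.05),
    "p_open_thorax": (0.55, 0.08, 0.15, 0.02),
    # multiplicative shift of the renal analytes (creatinine, urea)
    "renal_shift": (1.40, 1.00, 1.10, 0.95),
}

_HLM_PROBS = {
    "UVHD I": (0.05, 0.10, 0.85),
    "UVHD II": (0.10, 0.20, 0.70),
    "BVHD cmplx.": (0.10, 0.15, 0.75),
    "BVHD smpl.": (0.15, 0.17, 0.68),
}
_HYPOTHERMIA_PROBS = {
    "UVHD I": (0.05, 0.15, 0.80),
    "UVHD II": (0.30, 0.40, 0.30),
    "BVHD cmplx.": (0.15, 0.30, 0.55),
    "BVHD smpl.": (0.28, 0.39, 0.33),
}
HLM_CATEGORIES = ("0 min", ">=1-<90 min", ">=90 min")
HYPOTHERMIA_CATEGORIES = (">32 C", ">=28-<=32 C", "<28 C")

# Relative frequencies of historical group labels among patients with any
# previous CHD-related hospitalization.
_HISTORY_PROBS = (0.21, 0.13, 0.46, 0.02, 0.18)


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of the synthetic cohort.

    Parameters
    ----------
    group_sizes
        Patients per disease group.
    beta
        Planted log-hazard effects.  Continuous predictors are standardized
        over the generated cohort before the effect is applied (so betas are
        per standard deviation); binary/indicator predictors enter as 0/1.
        Keys of the form ``"disease_group:UVHD I"`` denote group membership
        indicators.
    baseline_scale_per_group
        Weibull scale (days) of the latent death time per group; smaller
        scale means earlier death and hence higher in-hospital mortality.
    weibull_shape
        Shared Weibull shape of the death-time law.
    discharge_lognormal_params_per_group
        ``(mu, sigma)`` of log discharge days per group.
    missingness_rates
        Per raw-field MCAR missingness fractions.
    seed
        Base seed; the generator is bit-reproducible given the spec.
    """

    group_sizes: Mapping[str, int]
    beta: Mapping[str, float]
    baseline_scale_per_group: Mapping[str, float]
    weibull_shape: float
    discharge_lognormal_params_per_group: Mapping[str, tuple[float, float]]
    missingness_rates: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in DISEASE_GROUPS:
                raise ValueError(f"unknown disease group in group_sizes: {g!r}")
            if int(n) <= 0:
                raise ValueError(f"group_sizes[{g!r}] must be positive, got {n}")
        for g, s in self.baseline_scale_per_group.items():
            if s <= 0:
                raise ValueError(f"baseline_scale_per_group[{g!r}] must be positive, got {s}")
        if self.weibull_shape <= 0:
            raise ValueError(f"weibull_shape must be positive, got {self.weibull_shape}")
        for g in self.group_sizes:
            if g not in self.baseline_scale_per_group:
                raise ValueError(f"baseline_scale_per_group missing group {g!r}")
            if g not in self.discharge_lognormal_params_per_group:
                raise ValueError(f"discharge_lognormal_params_per_group missing group {g!r}")
        for f_, r in self.missingness_rates.items():
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"missingness_rates[{f_!r}] must lie in [0, 1], got {r}")


# Weibull scales calibrated by Monte Carlo (bisection on the per-group
# death fraction at n = 200_000 per group) so that, under the default betas
# and covariate marginals, per-group mortality lands on 62/7.2/9.6/0.7 %.
_CALIBRATED_SCALES = {
    "UVHD I": 171.4,
    "UVHD II": 1402.5,
    "BVHD cmplx.": 1128.2,
    "BVHD smpl.": 13559.4,
}

_DEFAULT_BETA = {
    "creatinine_max": 2.0,
    "open_thorax": 0.9,
    "circulatory_arrest": 0.6,
    "disease_group:UVHD I": 0.4,
}

_DISCHARGE_PARAMS = {
    # medians 17 / 14 / 10 / 6 days; sigmas from the interquartile spread
    "UVHD I": (np.log(17.0), 1.10),
    "UVHD II": (np.log(14.0), 0.99),
    "BVHD cmplx.": (np.log(10.0), 0.66),
    "BVHD smpl.": (np.log(6.0), 0.35),
}


def default_spec(seed: int = 0) -> CohortSpec:
    """The study-condition spec: 1302 patients, planted creatinine effect."""
    return CohortSpec(
        group_sizes={"UVHD I": 50, "UVHD II": 111, "BVHD cmplx.": 291, "BVHD smpl.": 850},
        beta=dict(_DEFAULT_BETA),
        baseline_scale_per_group=dict(_CALIBRATED_SCALES),
        weibull_shape=1.0,
        discharge_lognormal_params_per_group=dict(_DISCHARGE_PARAMS),
        missingness_rates={"weight": 0.0223, "height": 0.0008},
        seed=seed,
    )


def _gp(key: str, gi: int) -> float:
    return _GROUP_PARAMS[key][gi]


def _lognormal_med(rng: np.random.Generator, median: float, sigma: float, size: int) -> np.ndarray:
    return np.exp(rng.normal(np.log(median), sigma, size=size))


def _draw_lab_series(
    rng: np.random.Generator,
    latent: np.ndarray,
    draw_sigma: float,
) -> list[list[tuple[float, float]]]:
    """4-8 (hour, value) draws per patient within the 72 h window."""
    n = len(latent)
    k = rng.integers(4, 9, size=n)
    total = int(k.sum())
    seg = np.repeat(np.arange(n), k)
    hours = rng.uniform(0.0, 72.0, size=total)
    order = np.lexsort((hours, seg))
    hours = np.round(hours[order], 2)
    values = np.round(np.repeat(latent, k) * np.exp(rng.normal(0.0, draw_sigma, size=total)), 4)
    bounds = np.cumsum(k)[:-1]
    return [
        list(zip(h.tolist(), v.tolist()))
        for h, v in zip(np.split(hours, bounds), np.split(values, bounds))
    ]


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate one raw cohort table, one row per patient.

    Raw columns mirror what a hospital extract would contain: demographics,
    disease-group assignment and history, surgery descriptors, per-analyte
    72 h lab series (lists of ``(hour, value)`` pairs), and the survival
    outcome (``followup_days``, ``status``).

    The drawn latent death and discharge times are also returned
    (``_death_time``, ``_discharge_time``) for calibration and testing; they
    are not part of the modeling surface.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    frames = []
    offset = 0
    for g in DISEASE_GROUPS:
        if g not in spec.group_sizes:
            continue
        n = int(spec.group_sizes[g])
        gi = DISEASE_GROUPS.index(g)
        df = pd.DataFrame(index=range(offset, offset + n))
        df["patient_id"] = [f"P{idx:05d}" for idx in df.index]
        df["disease_group"] = g
        df["sex"] = np.where(rng.random(n) < _gp("p_male", gi), "m", "w")
        age_adm = np.clip(
            np.exp(rng.normal(np.log(_gp("age_median", gi) + 1.0), _gp("age_sigma", gi), n)) - 1.0,
            0.0,
            6570.0,
        )
        df["age_at_admission"] = np.round(age_adm, 1)
        days_as = np.clip(
            np.round(
                np.exp(
                    rng.normal(
                        np.log(_gp("days_adm_surg_median", gi) + 0.5),
                        _gp("days_adm_surg_sigma", gi),
                        n,
                    )
                )
                - 0.5
            ),
            0.0,
            90.0,
        )
        df["days_admission_to_surgery"] = days_as
        df["age_at_surgery"] = np.round(age_adm + days_as, 1)
        df["weight"] = np.round(_lognormal_med(rng, _gp("weight_median", gi), _gp("weight_sigma", gi), n), 0)
        df["height"] = np.round(_lognormal_med(rng, _gp("height_median", gi), _gp("height_sigma", gi), n), 1)

        n_prev = rng.poisson(_gp("prev_adm_lambda", gi), size=n)
        df["n_previous_admissions"] = n_prev
        total_prev = int(n_prev.sum())
        draws = rng.choice(len(HISTORY_GROUPS), size=total_prev, p=_HISTORY_PROBS)
        labels = np.asarray(HISTORY_GROUPS, dtype=object)[draws]
        df["history_groups"] = [
            chunk.tolist() for chunk in np.split(labels, np.cumsum(n_prev)[:-1])
        ]

        for flag in ("malformations", "chrom_alterations", "pulm_hypertension", "circulatory_arrest", "open_thorax"):
            df[flag] = (rng.random(n) < _gp(f"p_{flag}", gi)).astype(int)

        df["hlm_category"] = rng.choice(HLM_CATEGORIES, size=n, p=_HLM_PROBS[g])
        df["hypothermia_category"] = rng.choice(HYPOTHERMIA_CATEGORIES, size=n, p=_HYPOTHERMIA_PROBS[g])
        # no bypass implies no aortic cross clamping
        clamp = np.round(rng.gamma(1.6, 45.0, size=n), 0)
        clamp[df["hlm_category"].to_numpy() == HLM_CATEGORIES[0]] = 0.0
        df["aortic_cross_clamp_time"] = clamp

        shift = _gp("renal_shift", gi)
        renal = rng.normal(0.0, 1.0, n)  # shared renal factor: creatinine/urea co-move
        lat_creat = np.exp(np.log(0.38 * shift) + 0.40 * renal * 0.8 + 0.40 * rng.normal(0, 0.6, n))
        lat_urea = np.exp(np.log(28.0 * shift) + 0.45 * renal * 0.25 + 0.45 * rng.normal(0, 0.968, n))
        lat_crp = np.exp(rng.normal(np.log(45.0), 0.70, n))
        lat_leuk = np.exp(rng.normal(np.log(10.5), 0.33, n))
        df["lab_creatinine"] = _draw_lab_series(rng, lat_creat, 0.15)
        df["lab_urea"] = _draw_lab_series(rng, lat_urea, 0.15)
        df["lab_crp"] = _draw_lab_series(rng, lat_crp, 0.20)
        df["lab_leukocytes"] = _draw_lab_series(rng, lat_leuk, 0.10)

        frames.append(df)
        offset += n

    cohort = pd.concat(frames).reset_index(drop=True)
    n_total = len(cohort)

    # --- survival mechanism -------------------------------------------------
    eta = np.zeros(n_total)
    creat_max = np.array([max(v for _, v in series) for series in cohort["lab_creatinine"]])
    continuous_pool = {
        "creatinine_max": creat_max,
        "urea_max": np.array([max(v for _, v in s) for s in cohort["lab_urea"]]),
        "crp_max": np.array([max(v for _, v in s) for s in cohort["lab_crp"]]),
        "leukocytes_min": np.array([min(v for _, v in s) for s in cohort["lab_leukocytes"]]),
        "age_at_surgery": cohort["age_at_surgery"].to_numpy(float),
        "aortic_cross_clamp_time": cohort["aortic_cross_clamp_time"].to_numpy(float),
        "days_admission_to_surgery": cohort["days_admission_to_surgery"].to_numpy(float),
        "weight": cohort["weight"].to_numpy(float),
    }
    for name, b in spec.beta.items():
        if b == 0.0:
            continue
        if name.startswith("disease_group:"):
            x = (cohort["disease_group"] == name.split(":", 1)[1]).to_numpy(float)
        elif name in continuous_pool:
            v = continuous_pool[name]
            sd = v.std()
            x = (v - v.mean()) / sd if sd > 0 else np.zeros(n_total)
        elif name in cohort.columns:
            x = cohort[name].to_numpy(float)
        else:
            raise ValueError(f"beta refers to unknown predictor {name!r}")
        eta = eta + b * x

    shape = spec.weibull_shape
    scales = cohort["disease_group"].map(spec.baseline_scale_per_group).to_numpy(float)
    e = rng.exponential(1.0, n_total)
    death = scales * (e / np.exp(eta)) ** (1.0 / shape)
    mu = cohort["disease_group"].map(
        {g: p[0] for g, p in spec.discharge_lognormal_params_per_group.items()}
    ).to_numpy(float)
    sg = cohort["disease_group"].map(
        {g: p[1] for g, p in spec.discharge_lognormal_params_per_group.items()}
    ).to_numpy(float)
    discharge = np.exp(rng.normal(mu, sg))

    deceased = death <= discharge
    cohort["_death_time"] = death
    cohort["_discharge_time"] = discharge
    # follow-up at fractional-day resolution (timestamped admission systems)
    cohort["followup_days"] = np.round(np.where(deceased, death, discharge), 1)
    cohort["status"] = np.where(deceased, "deceased", "censored")
    return cohort


def inject_missingness(
    cohort: pd.DataFrame,
    rates: Mapping[str, float],
    seed: int,
) -> pd.DataFrame:
    """Set raw fields missing completely at random (MCAR).

    Each targeted field is blanked independently per patient with its rate.
    Returns a copy; the input is untouched.
    """
    for f_, r in rates.items():
        if f_ not in cohort.columns:
            raise ValueError(f"missingness rate given for unknown field {f_!r}")
        if not (0.0 <= r <= 1.0):
            raise ValueError(f"missingness rate for {f_!r} must lie in [0, 1], got {r}")
    out = cohort.copy()
    rng = np.random.default_rng(seed)
    for f_ in sorted(rates):
        mask = rng.random(len(out)) < rates[f_]
        out.loc[mask, f_] = np.nan
    return out


_SERIES_COLS = [f"lab_{a}" for a in LAB_ANALYTES]


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    """Write a raw cohort to CSV; lab series become JSON strings."""
    out = cohort.copy()
    for c in _SERIES_COLS + ["history_groups"]:
        if c in out.columns:
            out[c] = out[c].map(json.dumps)
    out.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    """Inverse of :func:`write_cohort_csv`."""
    df = pd.read_csv(path)
    for c in _SERIES_COLS:
        if c in df.columns:
            df[c] = df[c].map(lambda s: [tuple(p) for p in json.loads(s)])
    if "history_groups" in df.columns:
        df["history_groups"] = df["history_groups"].map(json.loads)
    return df


def spec_to_dict(spec: CohortSpec) -> dict:
    d = {
        "group_sizes": dict(spec.group_sizes),
        "beta": dict(spec.beta),
        "baseline_scale_per_group": dict(spec.baseline_scale_per_group),
        "weibull_shape": spec.weibull_shape,
        "discharge_lognormal_params_per_group": {
            g: list(p) for g, p in spec.discharge_lognormal_params_per_group.items()
        },
        "missingness_rates": dict(spec.missingness_rates),
        "seed": spec.seed,
    }
    return d


def spec_from_dict(d: Mapping) -> CohortSpec:
    return CohortSpec(
        group_sizes=dict(d["group_sizes"]),
        beta=dict(d.get("beta", {})),
        baseline_scale_per_group=dict(d["baseline_scale_per_group"]),
        weibull_shape=float(d["weibull_shape"]),
        discharge_lognormal_params_per_group={
            g: (float(p[0]), float(p[1]))
            for g, p in d["discharge_lognormal_params_per_group"].items()
        },
        missingness_rates=dict(d.get("missingness_rates", {})),
        seed=int(d.get("seed", 0)),
    )


def with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """A copy of *spec* with a different seed."""
    return replace(spec, seed=seed)
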