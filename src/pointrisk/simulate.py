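"""Synthetic diabetes cohorts with the structure the score analysis assumes.

The generator emulates a type 2 diabetes cohort of ~24,104 subjects followed
for ESRD over up to 10 years: risk-factor categories are drawn independently
per factor at the published marginal prevalences, age from a truncated
normal on [30, 84], and event times from an exponential hazard

    lambda(x) = lambda0 * exp(sum_i beta_i * (x_i - xbar_i))

centered at the covariate means so that ``lambda0`` is the event rate (per
person-year) of an average subject. Censoring is the minimum of an
administrative horizon and an exponential dropout time; the default dropout
rate makes the mean follow-up about 8.3 years, and the default baseline
hazard is calibrated so that about 5.06% of subjects develop ESRD.

Visit series for the CV metrics are generated by exact construction: visit
values are rescaled so the sample mean and SD — hence the adjusted CV —
land exactly on a target drawn inside the subject's assigned tertile band.
Real-data features deliberately not emulated: correlation between risk
factors, non-constant baseline hazard, informative censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

from .variation import CUTPOINT_PRESETS

__all__ = [
    "GeneratorConfig",
    "default_prevalences",
    "default_betas",
    "simulate_cohort",
    "simulate_visits",
    "expected_event_fraction",
    "calibrate_lambda0",
    "DEFAULT_BASELINE_HAZARD",
]

#: Baseline hazard (events per person-year at covariate means) calibrated by
#: bisection so the default configuration yields an event fraction of about
#: 5.06% under the default censoring (see calibrate_lambda0).
DEFAULT_BASELINE_HAZARD = 0.003984

#: Dropout rate (per year) making the mean follow-up about 8.3 years under
#: the 10-year administrative horizon.
DEFAULT_DROPOUT_RATE = 0.033


def _table3():
    from .tables import load_table3

    return load_table3()


def default_prevalences() -> dict[str, dict[str, float]]:
    """Published category proportions per factor (non-reference categories)."""
    t3 = _table3()
    out: dict[str, dict[str, float]] = {}
    for _, row in t3.iterrows():
        if row["factor"] == "age" or row["is_reference"] == 1:
            continue
        out.setdefault(row["factor"], {})[row["category"]] = float(row["mean_or_prop"])
    return out


def default_betas() -> dict[str, float]:
    """Published log-hazard coefficients, keyed by design-column name."""
    t3 = _table3()
    out: dict[str, float] = {}
    for _, row in t3.iterrows():
        if row["factor"] == "age":
            out["age"] = float(row["beta"])
        elif row["is_reference"] == 0:
            out[f"{row['factor']}[{row['category']}]"] = float(row["beta"])
    return out


@dataclass
class GeneratorConfig:
    """Cohort-generator settings; defaults encode the published cohort."""

    n_subjects: int = 24104
    covariate_prevalences: dict[str, dict[str, float]] = field(default_factory=default_prevalences)
    true_betas: dict[str, float] = field(default_factory=default_betas)
    age_mean_sd: tuple[float, float] = (61.03, 10.77)
    age_range: tuple[float, float] = (30.0, 84.0)
    baseline_hazard: float = DEFAULT_BASELINE_HAZARD
    admin_censor_years: float = 10.0
    dropout_rate: float = DEFAULT_DROPOUT_RATE
    seed: int | None = None

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be at least 2")
        if not np.isfinite(list(self.true_betas.values())).all():
            raise ValueError("non-finite coefficient in true_betas")
        for factor, cats in self.covariate_prevalences.items():
            probs = np.array(list(cats.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError(f"probabilities of {factor!r} outside [0, 1]")
            if probs.sum() > 1.0 + 1e-9:
                raise ValueError(f"category probabilities of {factor!r} sum beyond 1")
        if self.baseline_hazard < 0 or not np.isfinite(self.baseline_hazard):
            raise ValueError("baseline_hazard must be finite and non-negative")
        if self.dropout_rate < 0:
            raise ValueError("dropout_rate must be non-negative")
        if not self.admin_censor_years > 0:
            raise ValueError("admin_censor_years must be positive")

    # -- io --------------------------------------------------------------
    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        d["age_mean_sd"] = list(self.age_mean_sd)
        d["age_range"] = list(self.age_range)
        s = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_yaml(cls, source) -> "GeneratorConfig":
        if hasattr(source, "read"):
            d = yaml.safe_load(source)
        else:
            s = str(source)
            if "\n" in s or s.lstrip().startswith(("{", "n_subjects")):
                d = yaml.safe_load(s)
            else:
                with open(s) as fh:
                    d = yaml.safe_load(fh)
        d["age_mean_sd"] = tuple(d.get("age_mean_sd", (61.03, 10.77)))
        d["age_range"] = tuple(d.get("age_range", (30.0, 84.0)))
        return cls(**d)


def _draw_covariates(config: GeneratorConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    mu, sd = config.age_mean_sd
    lo, hi = config.age_range
    a, b = (lo - mu) / sd, (hi - mu) / sd
    age = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=n, random_state=rng)
    cols = {"age": age}
    for factor, cats in config.covariate_prevalences.items():
        labels = ["__ref__"] + list(cats)
        probs = np.array([1.0 - sum(cats.values())] + list(cats.values()))
        probs = np.clip(probs, 0.0, None)
        probs /= probs.sum()
        cols[factor] = rng.choice(labels, size=n, p=probs)
    # numeric diabetes-history columns (imputation predictors): duration of
    # diagnosed diabetes ~ truncated normal, onset age = age - duration
    duration = np.maximum(rng.normal(6.66, 6.34, size=n), 0.0)
    cols["duration_years"] = duration
    cols["onset_age_years"] = np.maximum(age - duration, 18.0)
    df = pd.DataFrame(cols)
    # name the reference category per factor (first fixture category)
    from .model import default_terms

    refs = {t.factor: t.reference for t in default_terms() if not t.is_continuous}
    for factor in config.covariate_prevalences:
        ref = refs.get(factor, "ref")
        df[factor] = df[factor].replace("__ref__", ref)
    return df


def _linear_predictor(df: pd.DataFrame, config: GeneratorConfig) -> np.ndarray:
    eta = np.zeros(len(df))
    for col, beta in config.true_betas.items():
        if "[" in col:
            factor, cat = col[:-1].split("[", 1)
            prev = config.covariate_prevalences.get(factor, {}).get(cat, 0.0)
            eta += beta * ((df[factor].to_numpy() == cat).astype(float) - prev)
        else:
            center = config.age_mean_sd[0] if col == "age" else float(df[col].mean())
            eta += beta * (df[col].to_numpy(dtype=float) - center)
    return eta


def simulate_cohort(config: GeneratorConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a cohort: covariates, exponential event times, censoring.

    Deterministic under a fixed seed (``seed`` overrides ``config.seed``).
    Returns one row per subject with ``id``, ``age``, one category column
    per factor, ``follow_time`` (years) and ``event`` (0/1).
    """
    config = config if config is not None else GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(seed if seed is not None else config.seed)
    df = _draw_covariates(config, rng)
    n = len(df)
    lam = config.baseline_hazard * np.exp(_linear_predictor(df, config))
    with np.errstate(divide="ignore"):
        T = np.where(lam > 0, rng.exponential(size=n) / np.where(lam > 0, lam, 1.0), np.inf)
    if config.dropout_rate > 0:
        C = np.minimum(config.admin_censor_years, rng.exponential(1.0 / config.dropout_rate, n))
    else:
        rng.exponential(size=n)  # keep the stream aligned across dropout settings
        C = np.full(n, config.admin_censor_years)
    df.insert(0, "id", np.arange(1, n + 1))
    df["follow_time"] = np.minimum(T, C)
    df["event"] = (T <= C).astype(int)
    return df


def expected_event_fraction(
    config: GeneratorConfig,
    baseline_hazard: float | None = None,
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Event probability under the generator, by closed form over a
    Monte-Carlo draw of covariates only.

    With hazard lambda and censoring min(admin A, Exp(rho)),
    P(event | lambda) = lambda/(lambda+rho) * (1 - exp(-(lambda+rho) A)).
    """
    lam0 = config.baseline_hazard if baseline_hazard is None else baseline_hazard
    sub = GeneratorConfig(**{**asdict(config), "n_subjects": n_mc})
    sub.covariate_prevalences = config.covariate_prevalences
    sub.true_betas = config.true_betas
    rng = np.random.default_rng(seed)
    df = _draw_covariates(sub, rng)
    lam = lam0 * np.exp(_linear_predictor(df, sub))
    rho = config.dropout_rate
    A = config.admin_censor_years
    tot = lam + rho
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(tot > 0, lam / np.where(tot > 0, tot, 1.0) * -np.expm1(-tot * A), 0.0)
    return float(p.mean())


def calibrate_lambda0(
    config: GeneratorConfig | None = None,
    target_event_fraction: float = 0.0506,
    bracket: tuple[float, float] = (1e-6, 1.0),
    n_mc: int = 100_000,
    seed: int = 0,
) -> float:
    """Baseline hazard that hits a target event fraction, by bisection.

    Uses one fixed covariate draw so the objective is monotone and the
    root-find deterministic.
    """
    config = config if config is not None else GeneratorConfig()
    f = lambda lam0: expected_event_fraction(config, lam0, n_mc=n_mc, seed=seed) - target_event_fraction
    return float(optimize.brentq(f, *bracket, xtol=1e-8))


# -- visit-level series ----------------------------------------------------

#: Per-measure defaults: cohort column holding the assigned tertile,
#: tertile cutpoints (%), and the distribution of subject-level means.
VISIT_MEASURES = {
    "hba1c": {"group_col": "hba1c_cv", "cutpoints": CUTPOINT_PRESETS[("hba1c", "table3")],
              "mean": 8.18, "mean_sd": 1.92, "mean_floor": 4.0},
    "sbp": {"group_col": "sbp_cv", "cutpoints": CUTPOINT_PRESETS[("sbp", "table3")],
            "mean": 134.8, "mean_sd": 17.71, "mean_floor": 80.0},
}


def _target_band(group: str, c1: float, c2: float) -> tuple[float, float]:
    if group == "low":
        return 0.0, c1
    if group == "mid":
        return c1, c2
    if group == "high":
        return c2, c2 + (c2 - c1)
    raise ValueError(f"unknown tertile label {group!r}")


def simulate_visits(
    cohort: pd.DataFrame,
    n_visits_range: tuple[int, int] = (3, 8),
    measures: dict | None = None,
    dispersion_scale: float = 1.0,
    missing_rate: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """First-year visit values whose adjusted CV lands in the assigned band.

    For each subject and measure, a target adjusted CV is drawn uniformly
    inside the subject's tertile band and the visit values are constructed
    with exactly that sample CV (values are rescaled standard-normal draws
    around a subject mean). ``dispersion_scale`` rescales all targets
    (0 gives constant series, CV = 0); ``missing_rate`` assigns a fraction
    of subjects a single visit, whose CV is then missing downstream.

    Returns a long table (subject_id, measure, visit_index, value).
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    lo, hi = n_visits_range
    if hi < 1 or lo < 1 or hi < lo:
        raise ValueError("invalid n_visits_range")
    measures = measures if measures is not None else VISIT_MEASURES
    rng = np.random.default_rng(seed)
    out = []
    for measure, spec in measures.items():
        gcol = spec["group_col"]
        if gcol not in cohort.columns:
            raise KeyError(f"cohort lacks tertile column {gcol!r}")
        c1, c2 = spec["cutpoints"]
        n_sub = len(cohort)
        n_vis = rng.integers(lo, hi + 1, size=n_sub)
        if missing_rate > 0:
            n_vis = np.where(rng.random(n_sub) < missing_rate, 1, n_vis)
        mu = np.maximum(
            rng.normal(spec["mean"], spec["mean_sd"], size=n_sub), spec["mean_floor"]
        )
        for sid, grp, n, m in zip(cohort["id"], cohort[gcol].astype(str), n_vis, mu):
            if n == 1:
                vals = np.array([m])
            else:
                blo, bhi = _target_band(grp, c1, c2)
                target_adj = rng.uniform(blo, bhi) * dispersion_scale
                sd_target = target_adj * np.sqrt(n / (n - 1)) / 100.0 * m
                z = rng.standard_normal(n)
                u = z - z.mean()
                s = u.std(ddof=1)
                vals = m + (sd_target * u / s if s > 0 else 0.0)
                vals = np.maximum(vals, 1e-3)
            out.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "measure": measure,
                        "visit_index": np.arange(1, n + 1),
                        "value": vals,
                    }
                )
            )
    return pd.concat(out, ignore_index=True)
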