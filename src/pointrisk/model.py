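"""Proportional-hazards model building for the ESRD point score.

`CoxPointModel` wraps a cohort table plus a list of `TermSpec`s (indicator-
coded risk factors and continuous terms) and delegates partial-likelihood
maximisation to lifelines' `CoxPHFitter` (Efron tie handling). `fit()`
returns a `CoxPointResults` carrying everything the point system needs:
per-term coefficients and standard errors, covariate means, and baseline
survival S0(t) at the reporting horizons evaluated at the covariate means —
the quantities of the risk equation

    p(x, t) = 1 - S0(t) ** exp(sum_i beta_i * (x_i - xbar_i)).

Model building follows the usual screen-then-prune strategy: a univariable
screen at a permissive alpha, a collinearity check on the design matrix,
then backward elimination of whole factor blocks by likelihood-ratio test.
The proportional-hazards assumption is probed by refitting with follow-up
administratively censored at each horizon and comparing coefficients.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import stats

__all__ = [
    "TermSpec",
    "default_terms",
    "design_matrix",
    "CoxPointModel",
    "CoxPointResults",
    "fit_cox",
    "univariable_screen",
    "backward_select",
    "SelectionResult",
    "ph_check_by_censoring",
    "collinearity_screen",
    "km_loglog_data",
]

DEFAULT_HORIZONS = (3.0, 5.0, 8.0)


@dataclass(frozen=True)
class TermSpec:
    """One model term: a continuous column or an indicator-coded factor."""

    factor: str
    categories: tuple[str, ...] | None = None
    reference: str | None = None

    def __post_init__(self):
        if self.categories is not None:
            if len(set(self.categories)) != len(self.categories):
                raise ValueError(f"duplicate categories in factor {self.factor!r}")
            ref = self.reference if self.reference is not None else self.categories[0]
            if ref not in self.categories:
                raise ValueError(f"reference {ref!r} not among categories of {self.factor!r}")
            object.__setattr__(self, "reference", ref)

    @property
    def is_continuous(self) -> bool:
        return self.categories is None

    @property
    def columns(self) -> list[str]:
        if self.is_continuous:
            return [self.factor]
        return [f"{self.factor}[{c}]" for c in self.categories if c != self.reference]


def default_terms() -> list[TermSpec]:
    """Terms of the final published model, in fixture order.

    Age enters continuously (per year); the ten remaining factors are
    indicator-coded with the published reference categories.
    """
    from .tables import load_table3

    t3 = load_table3()
    terms: list[TermSpec] = []
    for factor, grp in t3.groupby("factor", sort=False):
        if factor == "age":
            terms.append(TermSpec("age"))
            continue
        cats = tuple(grp["category"])
        ref = grp.loc[grp["is_reference"] == 1, "category"]
        terms.append(TermSpec(factor, cats, ref.iloc[0] if len(ref) else cats[0]))
    return terms


def design_matrix(data: pd.DataFrame, terms: Sequence[TermSpec]) -> pd.DataFrame:
    """Float design matrix (no intercept) for the given terms."""
    cols = {}
    for term in terms:
        if term.factor not in data.columns:
            raise KeyError(f"cohort lacks column {term.factor!r}")
        if term.is_continuous:
            cols[term.factor] = data[term.factor].astype(float)
        else:
            vals = data[term.factor].astype(str)
            unknown = set(vals.unique()) - set(term.categories)
            if unknown:
                raise ValueError(f"unknown categories {sorted(unknown)} in {term.factor!r}")
            for cat in term.categories:
                if cat == term.reference:
                    continue
                cols[f"{term.factor}[{cat}]"] = (vals == cat).astype(float)
    return pd.DataFrame(cols, index=data.index)


@dataclass
class CoxPointResults:
    """Estimates, uncertainties and baseline survival from a Cox fit."""

    params: pd.Series
    bse: pd.Series
    covariate_means: pd.Series
    baseline_survival: dict[float, float]
    terms: list[TermSpec]
    n: int
    n_events: int
    log_likelihood: float
    model: "CoxPointModel | None" = None
    cph: CoxPHFitter | None = field(default=None, repr=False)

    def __post_init__(self):
        s = [self.baseline_survival[t] for t in sorted(self.baseline_survival)]
        if any(np.diff(s) > 1e-12) or not (0 < min(s) <= max(s) <= 1):
            raise ValueError(f"baseline survival not monotone in t or outside (0,1]: {s}")

    def summary(self) -> pd.DataFrame:
        """Per-coefficient table: beta, SE, z, p, HR with 95% CI."""
        z = self.params / self.bse
        p = 2.0 * stats.norm.sf(np.abs(z))
        ci = 1.959963984540054 * self.bse
        return pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "z": z,
                "p": p,
                "hr": np.exp(self.params),
                "hr_lower95": np.exp(self.params - ci),
                "hr_upper95": np.exp(self.params + ci),
            }
        )

    def linear_predictor(self, data: pd.DataFrame) -> pd.Series:
        """Centered linear predictor sum_i beta_i (x_i - xbar_i)."""
        X = design_matrix(data, self.terms)[self.params.index]
        return (X - self.covariate_means) @ self.params

    def predict_risk(self, data: pd.DataFrame, t: float) -> pd.Series:
        """Absolute event risk by horizon t per subject."""
        if t not in self.baseline_survival:
            raise KeyError(f"no baseline survival at t={t}; have {sorted(self.baseline_survival)}")
        s0 = self.baseline_survival[t]
        return 1.0 - s0 ** np.exp(self.linear_predictor(data))

    def confint(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def point_system(self, scheme=None, b_rule="5x_age_beta"):
        from .points import build_point_system

        return build_point_system(self, scheme=scheme, b_rule=b_rule)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "covariate_means": self.covariate_means.to_dict(),
            "baseline_survival": {str(t): s for t, s in self.baseline_survival.items()},
            "terms": [
                {
                    "factor": t.factor,
                    "categories": list(t.categories) if t.categories else None,
                    "reference": t.reference,
                }
                for t in self.terms
            ],
            "n": self.n,
            "n_events": self.n_events,
            "log_likelihood": self.log_likelihood,
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "CoxPointResults":
        order = list(d["params"])
        terms = [
            TermSpec(t["factor"], tuple(t["categories"]) if t["categories"] else None, t["reference"])
            for t in d["terms"]
        ]
        return cls(
            params=pd.Series(d["params"]).reindex(order),
            bse=pd.Series(d["bse"]).reindex(order),
            covariate_means=pd.Series(d["covariate_means"]).reindex(order),
            baseline_survival={float(t): s for t, s in d["baseline_survival"].items()},
            terms=terms,
            n=d["n"],
            n_events=d["n_events"],
            log_likelihood=d["log_likelihood"],
        )

    @classmethod
    def from_json(cls, source) -> "CoxPointResults":
        if hasattr(source, "read"):
            return cls.from_dict(json.load(source))
        s = str(source)
        if s.lstrip().startswith("{"):
            return cls.from_dict(json.loads(s))
        with open(s) as fh:
            return cls.from_dict(json.load(fh))


class CoxPointModel:
    """Cox proportional-hazards model of a cohort, ready for point scoring.

    Parameters
    ----------
    data : DataFrame
        One row per subject with the term columns plus follow-up time
        (years) and an event indicator.
    terms : list of TermSpec, optional
        Defaults to the published model's terms.
    horizons : sequence of float
        Years at which baseline survival is extracted (default 3, 5, 8).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        terms: Sequence[TermSpec] | None = None,
        duration_col: str = "follow_time",
        event_col: str = "event",
        horizons: Sequence[float] = DEFAULT_HORIZONS,
    ):
        self.terms = list(terms) if terms is not None else default_terms()
        self.duration_col = duration_col
        self.event_col = event_col
        self.horizons = tuple(float(h) for h in horizons)
        self.data = data
        if data[event_col].sum() < 2:
            raise ValueError("need at least two events to fit")
        X = design_matrix(data, self.terms)
        degenerate = [c for c in X.columns if X[c].nunique() < 2]
        if degenerate:
            raise ValueError(f"zero-variance design columns: {degenerate}")
        self._X = X

    @classmethod
    def from_dataframe(cls, data, terms=None, **kw) -> "CoxPointModel":
        return cls(data, terms=terms, **kw)

    def fit(self, **fit_kwargs) -> CoxPointResults:
        df = self._X.copy()
        df["__T"] = self.data[self.duration_col].astype(float).to_numpy()
        df["__E"] = self.data[self.event_col].astype(int).to_numpy()
        cph = CoxPHFitter()
        try:
            try:
                cph.fit(df, duration_col="__T", event_col="__E", **fit_kwargs)
            except Exception:
                # sparse cells can make the undamped Newton step overshoot;
                # retry with a conservative step size before giving up
                cph = CoxPHFitter()
                cph.fit(
                    df,
                    duration_col="__T",
                    event_col="__E",
                    fit_options={"step_size": 0.25},
                    **fit_kwargs,
                )
        except Exception as err:  # surface which factors are problematic
            diag = collinearity_screen(self.data, self.terms)
            raise RuntimeError(
                f"Cox fit failed ({err}); design diagnostics:\n{diag}"
            ) from err
        bs = cph.baseline_survival_
        times = bs.index.to_numpy(dtype=float)
        vals = bs.iloc[:, 0].to_numpy(dtype=float)

        def s0_at(t: float) -> float:
            i = np.searchsorted(times, t, side="right") - 1
            return float(vals[i]) if i >= 0 else 1.0

        return CoxPointResults(
            params=cph.params_.rename(None),
            bse=cph.standard_errors_.rename(None),
            covariate_means=self._X.mean(),
            baseline_survival={t: s0_at(t) for t in self.horizons},
            terms=self.terms,
            n=len(df),
            n_events=int(df["__E"].sum()),
            log_likelihood=float(cph.log_likelihood_),
            model=self,
            cph=cph,
        )


def fit_cox(
    data: pd.DataFrame,
    terms: Sequence[TermSpec] | None = None,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    **kw,
) -> CoxPointResults:
    """Fit the proportional-hazards model; see CoxPointModel."""
    return CoxPointModel(data, terms=terms, horizons=horizons, **kw).fit()


def _lrt_pvalue(ll_full: float, ll_reduced: float, df: int) -> float:
    return float(stats.chi2.sf(max(2.0 * (ll_full - ll_reduced), 0.0), df))


def univariable_screen(
    data: pd.DataFrame,
    terms: Sequence[TermSpec] | None = None,
    alpha: float = 0.25,
    **kw,
) -> tuple[list[TermSpec], pd.DataFrame]:
    """Single-term likelihood-ratio screen at a permissive alpha.

    Returns the terms whose single-term model rejects the null at
    ``p < alpha`` together with the per-term p-value table.
    """
    terms = list(terms) if terms is not None else default_terms()
    rows, retained = [], []
    for term in terms:
        res = fit_cox(data, [term], **kw)
        p = _lrt_pvalue(res.log_likelihood, _null_log_likelihood(res), len(term.columns))
        rows.append({"factor": term.factor, "df": len(term.columns), "p": p})
        if p < alpha:
            retained.append(term)
    return retained, pd.DataFrame(rows)


def _null_log_likelihood(res: CoxPointResults) -> float:
    """Partial log-likelihood of the same data at beta = 0."""
    lr = res.cph.log_likelihood_ratio_test()
    return res.log_likelihood - lr.test_statistic / 2.0


@dataclass
class SelectionResult:
    results: CoxPointResults | None
    retained: list[TermSpec]
    dropped: list[tuple[str, float]]
    empty: bool = False


def backward_select(
    data: pd.DataFrame,
    terms: Sequence[TermSpec] | None = None,
    alpha_stay: float = 0.05,
    **kw,
) -> SelectionResult:
    """Backward elimination of whole factor blocks by likelihood-ratio test.

    At each step the block with the largest p is removed if p >= alpha_stay,
    and the model is refitted. An empty final model is allowed and flagged.
    """
    current = list(terms) if terms is not None else default_terms()
    dropped: list[tuple[str, float]] = []
    while current:
        full = fit_cox(data, current, **kw)
        if len(current) == 1:
            pvals = {current[0].factor: _lrt_pvalue(
                full.log_likelihood, _null_log_likelihood(full), len(current[0].columns)
            )}
        else:
            pvals = {}
            for term in current:
                reduced = fit_cox(data, [t for t in current if t is not term], **kw)
                pvals[term.factor] = _lrt_pvalue(
                    full.log_likelihood, reduced.log_likelihood, len(term.columns)
                )
        worst = max(pvals, key=pvals.get)
        if pvals[worst] < alpha_stay:
            return SelectionResult(full, current, dropped)
        dropped.append((worst, pvals[worst]))
        current = [t for t in current if t.factor != worst]
    warnings.warn("backward elimination removed every factor; model is empty")
    return SelectionResult(None, [], dropped, empty=True)


def ph_check_by_censoring(
    data: pd.DataFrame,
    terms: Sequence[TermSpec] | None = None,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
    abs_tol: float = 0.5,
    rel_tol: float = 0.5,
    min_events: int = 10,
    duration_col: str = "follow_time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Coefficient stability under administrative censoring at each horizon.

    Refits the model with follow-up truncated at each horizon and reports
    the per-coefficient spread; a term is flagged when the spread exceeds
    ``abs_tol`` in absolute value AND ``rel_tol`` relative to the mean
    coefficient magnitude (both, so that noise on near-zero coefficients
    does not flag spuriously). With a single usable horizon no flags are
    possible.
    """
    terms = list(terms) if terms is not None else default_terms()
    betas = {}
    for h in horizons:
        trunc = data.copy()
        over = trunc[duration_col] > h
        trunc.loc[over, event_col] = 0
        trunc.loc[over, duration_col] = h
        if trunc[event_col].sum() < min_events:
            warnings.warn(f"horizon {h}: fewer than {min_events} events; skipped")
            continue
        betas[h] = fit_cox(
            trunc, terms, horizons=(h,), duration_col=duration_col, event_col=event_col
        ).params
    if not betas:
        raise ValueError("no horizon had enough events")
    tab = pd.DataFrame(betas)
    spread = tab.max(axis=1) - tab.min(axis=1)
    center = tab.abs().mean(axis=1)
    tab["spread"] = spread
    tab["flagged"] = (
        (spread > abs_tol) & (spread / np.maximum(center, 1e-12) > rel_tol)
        if tab.shape[1] > 2
        else False
    )
    return tab


def collinearity_screen(
    data: pd.DataFrame, terms: Sequence[TermSpec] | None = None, vif_threshold: float = 10.0
) -> pd.DataFrame:
    """Variance-inflation factors of the design matrix columns.

    Flags columns with VIF above the threshold; indicator blocks of the
    same factor naturally share variance and are judged as a block.
    """
    terms = list(terms) if terms is not None else default_terms()
    X = design_matrix(data, terms).to_numpy(dtype=float)
    names = design_matrix(data.head(1), terms).columns
    Xc = X - X.mean(axis=0)
    denom = Xc.std(axis=0)
    denom[denom == 0] = np.nan
    R = np.corrcoef(Xc, rowvar=False)
    try:
        vif = np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        vif = np.full(X.shape[1], np.inf)
    out = pd.DataFrame({"vif": vif}, index=names)
    out["flagged"] = out["vif"] > vif_threshold
    return out


def km_loglog_data(
    data: pd.DataFrame,
    factor: str,
    duration_col: str = "follow_time",
    event_col: str = "event",
) -> pd.DataFrame:
    """Data for the log(-log(survival)) graphical PH check, per stratum."""
    rows = []
    for level, grp in data.groupby(factor):
        km = KaplanMeierFitter().fit(grp[duration_col], grp[event_col])
        sf = km.survival_function_.iloc[:, 0]
        ok = (sf > 0) & (sf < 1)
        rows.append(
            pd.DataFrame(
                {
                    "stratum": str(level),
                    "time": sf.index[ok],
                    "neg_log_s": -np.log(sf[ok]),
                    "loglog": np.log(-np.log(sf[ok])),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
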