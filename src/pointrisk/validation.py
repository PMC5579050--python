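"""Discrimination, calibration and internal-validation metrics.

Horizon-specific metrics treat the outcome as binary "event by t":
subjects with an event at or before t are cases, subjects still under
observation beyond t are controls, and subjects censored before t without
an event are excluded by default (an inverse-probability-of-censoring
weighted variant is available for sensitivity).

Calibration-in-the-large and the calibration slope are measured on the
complementary-log-log scale of the predicted risk: a binomial GLM of the
observed indicator on cloglog(p-hat) with free slope gives the slope
(ideal 1), and with the slope fixed at one gives the intercept (ideal 0).
Bootstrap optimism correction follows the usual resampling recipe:
refit on each bootstrap sample, score the refit on both the bootstrap and
the original data, and subtract the mean difference from the apparent
performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

__all__ = [
    "DiscriminationResult",
    "HosmerLemeshowResult",
    "BootstrapOptimismResult",
    "horizon_mask",
    "horizon_auc",
    "hosmer_lemeshow",
    "calibration_cloglog",
    "horizon_calibration",
    "bootstrap_optimism",
    "incidence_rate",
    "standardized_difference",
    "split_cohort",
]


def horizon_mask(time, event, t: float) -> tuple[np.ndarray, np.ndarray]:
    """(evaluable mask, binary outcome) for horizon t.

    Cases: event by t. Controls: observed beyond t. Censored before t
    without event: not evaluable.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    case = (event == 1) & (time <= t)
    control = time > t
    return case | control, case.astype(int)


def _censoring_weights(time, event, t: float) -> np.ndarray:
    """IPCW weights from the Kaplan-Meier estimate of the censoring law."""
    from lifelines import KaplanMeierFitter

    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    km = KaplanMeierFitter().fit(time, 1 - event)
    sf = km.survival_function_.iloc[:, 0]
    grid, vals = sf.index.to_numpy(dtype=float), sf.to_numpy(dtype=float)

    def G(u):
        i = np.searchsorted(grid, u, side="right") - 1
        g = np.where(i >= 0, vals[np.clip(i, 0, len(vals) - 1)], 1.0)
        return np.maximum(g, 1e-8)

    w = np.zeros_like(time)
    case = (event == 1) & (time <= t)
    control = time > t
    w[case] = 1.0 / G(time[case])
    w[control] = 1.0 / G(np.full(control.sum(), t))
    return w


def _delong_variance(case_scores: np.ndarray, control_scores: np.ndarray) -> float:
    """Variance of the Mann-Whitney AUC by DeLong's structural components."""
    m, n = len(case_scores), len(control_scores)
    all_scores = np.concatenate([case_scores, control_scores])
    rank_all = stats.rankdata(all_scores)
    rank_case = stats.rankdata(case_scores)
    rank_control = stats.rankdata(control_scores)
    v10 = (rank_all[:m] - rank_case) / n  # per-case placement values
    v01 = 1.0 - (rank_all[m:] - rank_control) / m
    return np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n


@dataclass(frozen=True)
class DiscriminationResult:
    horizon: float
    auc: float
    ci_lower: float
    ci_upper: float
    n: int
    n_cases: int
    method: str = "exclude"


def horizon_auc(risks, time, event, t: float, method: str = "exclude") -> DiscriminationResult:
    """AUC of predicted risk against event-by-t, with a DeLong-type 95% CI.

    ``method="ipcw"`` weights evaluable subjects by the inverse censoring
    survival instead of plain exclusion (CI omitted for that variant).
    """
    risks = np.asarray(risks, dtype=float)
    mask, y = horizon_mask(time, event, t)
    y, r = y[mask], risks[mask]
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(f"no evaluable cases or no controls at t={t}")
    if method == "ipcw":
        w = _censoring_weights(time, event, t)[mask]
        auc = roc_auc_score(y, r, sample_weight=w)
        lo = hi = np.nan
    elif method == "exclude":
        auc = roc_auc_score(y, r)
        var = _delong_variance(r[y == 1], r[y == 0])
        half = 1.959963984540054 * np.sqrt(var)
        lo, hi = max(auc - half, 0.0), min(auc + half, 1.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    return DiscriminationResult(t, float(auc), float(lo), float(hi), int(mask.sum()), int(y.sum()), method)


@dataclass(frozen=True)
class HosmerLemeshowResult:
    chi2: float
    p: float
    df: int
    table: pd.DataFrame  # per group: n, observed, expected, mean_risk


def hosmer_lemeshow(risks, observed=None, time=None, event=None, t: float | None = None,
                    groups: int = 10, df_reduction: int = 2) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit over predicted-risk deciles.

    Pass either a binary ``observed`` vector, or ``time``/``event``/``t``
    for the horizon outcome with censored-before-t subjects excluded.
    chi2 = sum (O-E)^2 / (E (1 - E/n_g)), df = groups - df_reduction.
    The default df_reduction of 2 is the classical reference for risks
    estimated on the data being tested; for externally fixed risks the
    chi-square reference has the full ``groups`` degrees of freedom
    (``df_reduction=0``). Groups whose expected count is zero are merged
    into their neighbor with a warning.
    """
    risks = np.asarray(risks, dtype=float)
    if observed is None:
        if time is None or event is None or t is None:
            raise ValueError("need observed, or time/event/t")
        mask, y = horizon_mask(time, event, t)
        risks, y = risks[mask], y[mask]
    else:
        y = np.asarray(observed, dtype=int)
    order = np.argsort(risks, kind="mergesort")
    edges = np.array_split(order, groups)
    bins = [b for b in edges if len(b)]
    rows = [
        {"n": len(b), "observed": int(y[b].sum()), "expected": float(risks[b].sum()),
         "mean_risk": float(risks[b].mean())}
        for b in bins
    ]
    # merge zero-expectation groups into the next one up
    merged = []
    for row in rows:
        if merged and (merged[-1]["expected"] == 0.0):
            warnings.warn("merging group with zero expected events into neighbor")
            last = merged.pop()
            row = {
                "n": last["n"] + row["n"],
                "observed": last["observed"] + row["observed"],
                "expected": last["expected"] + row["expected"],
                "mean_risk": (last["mean_risk"] * last["n"] + row["mean_risk"] * row["n"])
                / (last["n"] + row["n"]),
            }
        merged.append(row)
    table = pd.DataFrame(merged)
    if (table["expected"] == 0).any() or len(table) < 2:
        raise ValueError("need at least two groups with nonzero expected events")
    O, E, ng = table["observed"].to_numpy(), table["expected"].to_numpy(), table["n"].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = (O - E) ** 2 / (E * (1.0 - E / ng))
    contrib = np.where(E >= ng, (O - E) ** 2 / E, contrib)  # guard saturated group
    chi2 = float(np.sum(contrib))
    df = max(len(table) - df_reduction, 1)
    return HosmerLemeshowResult(chi2, float(stats.chi2.sf(chi2, df)), df, table)


def _cloglog(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(-np.log1p(-p))


def calibration_cloglog(risks, observed, weights=None) -> tuple[float, float]:
    """(calibration-in-the-large intercept, calibration slope).

    Binomial GLM with cloglog link of the observed indicator on
    cloglog(predicted risk); the intercept is estimated with the slope
    fixed at 1 (as an offset). Ideal values are 0 and 1. ``weights``
    (typically IPCW) correct for informatively excluded subjects.
    """
    x = _cloglog(np.asarray(risks, dtype=float))
    y = np.asarray(observed, dtype=float)
    kw = {} if weights is None else {"var_weights": np.asarray(weights, dtype=float)}
    fam = sm.families.Binomial(link=sm.families.links.CLogLog())
    slope = sm.GLM(y, sm.add_constant(x), family=fam, **kw).fit().params[1]
    intercept = sm.GLM(y, np.ones_like(y), family=fam, offset=x, **kw).fit().params[0]
    return float(intercept), float(slope)


def horizon_calibration(risks, time, event, t: float) -> tuple[float, float]:
    """Calibration pair at horizon t with IPCW-corrected exclusion.

    Subjects censored before t are excluded, which keeps every case but
    only the controls still under observation; inverse-probability-of-
    censoring weights undo the resulting case over-representation.
    """
    risks = np.asarray(risks, dtype=float)
    mask, y = horizon_mask(time, event, t)
    w = _censoring_weights(time, event, t)[mask]
    return calibration_cloglog(risks[mask], y[mask], weights=w)


@dataclass(frozen=True)
class BootstrapOptimismResult:
    apparent_intercept: float
    apparent_slope: float
    corrected_intercept: float
    corrected_slope: float
    optimism_intercept: float
    optimism_slope: float
    mae_intercept: float
    mae_slope: float
    b_reps: int
    n_failed: int


def bootstrap_optimism(
    data: pd.DataFrame,
    terms=None,
    t: float = 5.0,
    b_reps: int = 1000,
    seed: int | None = None,
    duration_col: str = "follow_time",
    event_col: str = "event",
) -> BootstrapOptimismResult:
    """Optimism-corrected calibration intercept and slope.

    Per replicate the model is refitted on a bootstrap resample; the
    calibration pair is computed on the resample (apparent for that refit)
    and on the original data (test), and the mean difference is subtracted
    from the full-data apparent values. Non-convergent replicates are
    skipped and counted. ``b_reps=0`` returns the apparent values.
    """
    from .model import fit_cox

    def calib_pair(fitres, df):
        risks = fitres.predict_risk(df, t).to_numpy()
        return horizon_calibration(risks, df[duration_col], df[event_col], t)

    full = fit_cox(data, terms, horizons=(t,), duration_col=duration_col, event_col=event_col)
    a_app, s_app = calib_pair(full, data)
    rng = np.random.default_rng(seed)
    diffs, maes, failed = [], [], 0
    for _ in range(b_reps):
        idx = rng.integers(0, len(data), size=len(data))
        boot = data.iloc[idx].reset_index(drop=True)
        try:
            fb = fit_cox(boot, terms, horizons=(t,), duration_col=duration_col, event_col=event_col)
            a_b, s_b = calib_pair(fb, boot)
            a_o, s_o = calib_pair(fb, data)
        except Exception:
            failed += 1
            continue
        diffs.append((a_b - a_o, s_b - s_o))
        maes.append((abs(a_b - a_o), abs(s_b - s_o)))
    if diffs:
        opt_a, opt_s = map(float, np.mean(diffs, axis=0))
        mae_a, mae_s = map(float, np.mean(maes, axis=0))
    else:
        opt_a = opt_s = mae_a = mae_s = 0.0
    return BootstrapOptimismResult(
        a_app, s_app, a_app - opt_a, s_app - opt_s, opt_a, opt_s, mae_a, mae_s, b_reps, failed
    )


def incidence_rate(events: float, person_years: float) -> float:
    """Incidence per 1000 person-years: 1000 * events / person-years."""
    if not person_years > 0:
        raise ValueError(f"person_years must be positive, got {person_years}")
    return 1000.0 * events / person_years


def standardized_difference(a, b, kind: str = "continuous") -> float:
    """Standardized effect size between two group summaries.

    ``kind="continuous"``: a, b are (mean, sd) pairs, effect =
    (m_a - m_b) / sqrt((sd_a^2 + sd_b^2) / 2). ``kind="binary"``: a, b are
    proportions, pooled SD = sqrt((p_a(1-p_a) + p_b(1-p_b)) / 2).
    """
    if kind == "continuous":
        (ma, sa), (mb, sb) = a, b
        pooled = np.sqrt((sa**2 + sb**2) / 2.0)
    elif kind == "binary":
        pa, pb = float(a), float(b)
        pooled = np.sqrt((pa * (1 - pa) + pb * (1 - pb)) / 2.0)
        ma, mb = pa, pb
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return float((ma - mb) / pooled)


def split_cohort(data: pd.DataFrame, ratio=(2, 1), seed: int | None = None):
    """Simple random derivation/validation split at the given ratio.

    The derivation set gets ceil(n * r) rows, so 24,104 at 2:1 splits
    16,070 / 8,034. Deterministic under a fixed seed.
    """
    n = len(data)
    if n < 3:
        raise ValueError("need at least 3 subjects to split")
    r = ratio[0] / (ratio[0] + ratio[1])
    n_der = int(np.ceil(n * r))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return (
        data.iloc[np.sort(perm[:n_der])].reset_index(drop=True),
        data.iloc[np.sort(perm[n_der:])].reset_index(drop=True),
    )
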