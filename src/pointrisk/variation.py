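"""Visit-to-visit variability metrics.

The variability measure used throughout the package is the coefficient of
variation (CV) of repeated within-first-year measurements (HbA1c in %, SBP
in mmHg), expressed in percent and adjusted for the number of visits:

    raw_cv      = 100 * SD / mean            (sample SD, n-1 denominator)
    adjusted_cv = raw_cv / sqrt(n / (n - 1))

The adjustment divides by sqrt(n/(n-1)) so that subjects with few visits are
not mechanically assigned larger variability. Subjects with fewer than two
visits have no computable CV and are flagged missing (NaN) rather than
raising; the missing-data stage consumes that signal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AdjustedCV",
    "adjusted_cv",
    "adjusted_cv_table",
    "assign_tertiles",
    "CUTPOINT_PRESETS",
    "TERTILE_LABELS",
]

TERTILE_LABELS = ("low", "mid", "high")

#: Named cutpoint presets for the adjusted-CV tertiles (percent).  The two
#: published presentations of the HbA1c-CV tertiles use different boundaries
#: (17.3/34.5 in the incidence table, 8.5/17.5 in the score table); both are
#: kept as presets rather than reconciled.
CUTPOINT_PRESETS: dict[tuple[str, str], tuple[float, float]] = {
    ("hba1c", "table2"): (17.3, 34.5),
    ("hba1c", "table3"): (8.5, 17.5),
    ("sbp", "table2"): (4.4, 8.7),
    ("sbp", "table3"): (4.4, 8.7),
}


@dataclass(frozen=True)
class AdjustedCV:
    """Adjusted coefficient of variation for one subject and measure."""

    subject_id: object
    measure: str
    n_visits: int
    raw_cv: float
    adjusted_cv: float

    @property
    def is_missing(self) -> bool:
        return self.n_visits < 2


def adjusted_cv(values, subject_id=None, measure: str = "") -> AdjustedCV:
    """Visit-count-adjusted CV (%) of a series of visit values.

    Parameters
    ----------
    values : array-like
        Ordered measurement values from repeated visits; must be positive
        with a positive mean when n >= 2.

    Returns
    -------
    AdjustedCV
        With ``raw_cv``/``adjusted_cv`` NaN when fewer than two visits are
        available (missing-CV signal, not an error).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        return AdjustedCV(subject_id, measure, n, np.nan, np.nan)
    mean = v.mean()
    if not mean > 0:
        raise ValueError(f"visit mean must be positive, got {mean!r}")
    raw = 100.0 * v.std(ddof=1) / mean
    return AdjustedCV(subject_id, measure, n, raw, raw / np.sqrt(n / (n - 1)))


def adjusted_cv_table(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-subject adjusted CVs from a long-format visit table.

    ``visits`` needs columns ``subject_id``, ``measure``, ``value``
    (a ``visit_index`` column is allowed and ignored). Returns one row per
    (subject_id, measure) with n_visits, raw_cv, adjusted_cv; CVs are NaN
    for subjects with a single visit.
    """
    required = {"subject_id", "measure", "value"}
    missing = required - set(visits.columns)
    if missing:
        raise ValueError(f"visit table missing columns: {sorted(missing)}")

    def _one(g: pd.Series) -> pd.Series:
        r = adjusted_cv(g.to_numpy())
        return pd.Series(
            {"n_visits": r.n_visits, "raw_cv": r.raw_cv, "adjusted_cv": r.adjusted_cv}
        )

    out = (
        visits.groupby(["subject_id", "measure"], sort=True)["value"]
        .apply(_one)
        .unstack()
        .reset_index()
    )
    out["n_visits"] = out["n_visits"].astype(int)
    return out


def assign_tertiles(values, cutpoints="empirical", labels=TERTILE_LABELS):
    """Assign low/mid/high bands by two cutpoints or empirical tertiles.

    Bands are half-open ``[0, c1), [c1, c2), [c2, inf)``: a value exactly on
    a boundary goes to the upper band. ``cutpoints="empirical"`` uses the
    33.3/66.7 percentiles of the finite values. NaN values get NaN labels.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values to band")
    if isinstance(cutpoints, str):
        if cutpoints != "empirical":
            raise ValueError(f"unknown cutpoint mode {cutpoints!r}")
        finite = v[np.isfinite(v)]
        if finite.size == 0:
            raise ValueError("all values missing; cannot form empirical tertiles")
        c1, c2 = np.percentile(finite, [100 / 3, 200 / 3])
        if c1 == c2:
            warnings.warn("degenerate empirical tertiles: boundaries coincide")
    else:
        c1, c2 = float(cutpoints[0]), float(cutpoints[1])
    if not c1 <= c2:
        raise ValueError(f"cutpoints must be ordered, got ({c1}, {c2})")
    idx = np.digitize(v, [c1, c2], right=False)  # boundary -> upper band
    out = pd.Categorical.from_codes(
        np.where(np.isnan(v), -1, idx).astype(int), categories=list(labels)
    )
    return out
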