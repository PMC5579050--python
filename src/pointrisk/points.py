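"""Framingham-style point system: coefficients -> integer points -> risk.

A fitted proportional-hazards model is converted to a clinical scoring sheet
in the usual way: each risk-factor category gets a representative value
W_ij (for continuous factors the interval midpoint; for indicator-coded
factors the indicator itself), a reference category with W_iREF, and

    points_ij = round((beta_i * (W_ij - W_iREF)) / B)

where the constant ``B`` is the amount of log-hazard worth one point —
by default five years of age effect, B = 5 * beta_age. A subject's total
score P maps back to absolute risk at horizon t through

    p(P, t) = 1 - S0(t) ** exp(B * P + c),
    c       = sum_i beta_i * W_iREF - sum_i beta_i * xbar_i,

with S0(t) the baseline survival at the covariate means xbar_i. The constant
c re-centers the score so that the all-reference profile corresponds to the
reference risk; only the product S0(t)**exp(c) is identified, so when a
system is rebuilt from published points alone, S0(t) is calibrated to an
anchor row with c = 0.

Rounding is to the nearest integer with halves away from zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "round_half_away",
    "ContinuousBinning",
    "CategoryScheme",
    "default_age_binning",
    "PointSystem",
    "build_point_system",
    "total_score",
    "risk_from_score",
    "build_risk_table",
    "s0_from_anchor",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (not banker's)."""
    return int(np.sign(x) * np.floor(abs(x) + 0.5))


@dataclass(frozen=True)
class ContinuousBinning:
    """Categorization of one continuous factor for point scoring.

    ``edges`` are the n+1 interval boundaries of n ordered categories;
    ``w`` holds the representative value of each category (midpoints for
    bounded intervals) and ``reference`` names the zero-point category.
    """

    factor: str
    labels: tuple[str, ...]
    edges: tuple[float, ...]
    w: dict[str, float]
    reference: str

    def __post_init__(self):
        if len(self.edges) != len(self.labels) + 1:
            raise ValueError("need len(labels)+1 edges")
        if self.reference not in self.labels:
            raise ValueError(f"reference {self.reference!r} not a label")

    @property
    def w_ref(self) -> float:
        return self.w[self.reference]

    def assign(self, values) -> pd.Categorical:
        v = np.asarray(values, dtype=float)
        idx = np.clip(np.digitize(v, self.edges[1:-1], right=False), 0, len(self.labels) - 1)
        return pd.Categorical.from_codes(idx, categories=list(self.labels))


@dataclass(frozen=True)
class CategoryScheme:
    """Scheme describing how factors are categorized for scoring.

    Indicator-coded factors score directly from their category coefficients
    and need no entry; continuous factors must appear in ``continuous``.
    """

    continuous: dict[str, ContinuousBinning] = field(default_factory=dict)


def default_age_binning() -> ContinuousBinning:
    """Five-year age categories on 30-84 with reference 40-44.

    Representative values are interval midpoints (32, 37, ..., 82); with
    B = 5 * beta_age the age points are exactly (midpoint - 42) / 5, i.e.
    -2 for 30-34 up to 8 for 80-84.
    """
    lows = list(range(30, 85, 5))
    labels = tuple(f"{lo}-{lo + 4}" for lo in lows)
    edges = tuple(float(x) for x in lows + [85])
    w = {lab: lo + 2.0 for lab, lo in zip(labels, lows)}
    return ContinuousBinning("age", labels, edges, w, "40-44")


def default_scheme() -> CategoryScheme:
    return CategoryScheme(continuous={"age": default_age_binning()})


@dataclass
class PointSystem:
    """Integer points per risk-factor category plus the points->risk map."""

    b: float
    points: dict[str, dict[str, int]]
    s0: dict[float, float]
    risk_constant: float = 0.0
    scheme: CategoryScheme = field(default_factory=CategoryScheme)
    betas: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.b > 0:
            raise ValueError(f"points constant B must be positive, got {self.b}")
        for t, s in self.s0.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"S0({t}) = {s} outside [0, 1]")

    # -- scoring ---------------------------------------------------------
    @property
    def horizons(self) -> tuple[float, ...]:
        return tuple(sorted(self.s0))

    @property
    def score_range(self) -> tuple[int, int]:
        lo = sum(min(p.values()) for p in self.points.values())
        hi = sum(max(p.values()) for p in self.points.values())
        return lo, hi

    def total_score(self, categories: Mapping[str, object]) -> int:
        """Sum of category points; requires every factor exactly once."""
        total = 0
        for factor, pts in self.points.items():
            if factor not in categories:
                raise KeyError(f"missing factor {factor!r}")
            cat = categories[factor]
            if factor in self.scheme.continuous and not isinstance(cat, str):
                cat = str(self.scheme.continuous[factor].assign([cat])[0])
            if cat not in pts:
                raise KeyError(f"unknown category {cat!r} for factor {factor!r}")
            total += pts[cat]
        return total

    def score_dataframe(self, data: pd.DataFrame) -> pd.Series:
        """Total score per row; continuous factors are binned via the scheme."""
        total = pd.Series(0, index=data.index, dtype=int)
        for factor, pts in self.points.items():
            if factor not in data.columns:
                raise KeyError(f"missing factor column {factor!r}")
            col = data[factor]
            if factor in self.scheme.continuous:
                col = pd.Series(
                    self.scheme.continuous[factor].assign(col.to_numpy()), index=data.index
                )
            mapped = col.astype(str).map(pts)
            if mapped.isna().any():
                bad = sorted(col.astype(str)[mapped.isna()].unique())
                raise KeyError(f"unknown categories {bad} for factor {factor!r}")
            total = total + mapped.astype(int)
        return total

    # -- risk mapping ----------------------------------------------------
    def risk(self, score, t: float):
        """Predicted event probability at horizon t for total score(s)."""
        if t not in self.s0:
            raise KeyError(f"no baseline survival at horizon {t}; have {self.horizons}")
        s0 = self.s0[t]
        p = 1.0 - np.power(s0, np.exp(self.b * np.asarray(score, dtype=float) + self.risk_constant))
        return np.clip(p, 0.0, 1.0) if np.ndim(score) else float(np.clip(p, 0.0, 1.0))

    # -- io ----------------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "b": self.b,
            "points": self.points,
            "s0": {str(t): s for t, s in self.s0.items()},
            "risk_constant": self.risk_constant,
            "betas": self.betas,
            "continuous": {
                f: {
                    "labels": list(c.labels),
                    "edges": list(c.edges),
                    "w": c.w,
                    "reference": c.reference,
                }
                for f, c in self.scheme.continuous.items()
            },
        }
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "PointSystem":
        scheme = CategoryScheme(
            continuous={
                f: ContinuousBinning(
                    f, tuple(c["labels"]), tuple(c["edges"]), dict(c["w"]), c["reference"]
                )
                for f, c in d.get("continuous", {}).items()
            }
        )
        return cls(
            b=d["b"],
            points={f: {k: int(v) for k, v in pts.items()} for f, pts in d["points"].items()},
            s0={float(t): s for t, s in d["s0"].items()},
            risk_constant=d.get("risk_constant", 0.0),
            scheme=scheme,
            betas=d.get("betas", {}),
        )

    @classmethod
    def from_json(cls, source) -> "PointSystem":
        if hasattr(source, "read"):
            d = json.load(source)
        else:
            s = str(source)
            if s.lstrip().startswith("{"):
                d = json.loads(s)
            else:
                with open(s) as fh:
                    d = json.load(fh)
        return cls.from_dict(d)


def build_point_system(fit, scheme: CategoryScheme | None = None, b_rule="5x_age_beta") -> PointSystem:
    """Convert a Cox fit into an integer point system.

    Parameters
    ----------
    fit : CoxPointResults
        Needs ``params`` (coefficients indexed ``factor[category]`` or the
        bare factor name for continuous terms), ``covariate_means``,
        ``baseline_survival`` (dict horizon -> S0) and ``terms``.
    scheme : CategoryScheme
        Binning for continuous factors; defaults to 5-year age bins.
    b_rule : "5x_age_beta" or float
        One point's worth of log-hazard. The default anchors the scale at
        five years of age effect, B = 5 * beta_age.
    """
    scheme = scheme if scheme is not None else default_scheme()
    params = fit.params
    if b_rule == "5x_age_beta":
        if "age" not in params.index:
            raise ValueError("b_rule='5x_age_beta' needs an 'age' term in the fit")
        b = 5.0 * float(params["age"])
    else:
        b = float(b_rule)
    if not b > 0:
        raise ValueError(f"points constant B must be positive, got {b}")

    points: dict[str, dict[str, int]] = {}
    betas: dict[str, dict[str, float]] = {}
    c = 0.0
    for term in fit.terms:
        if term.is_continuous:
            if term.factor not in scheme.continuous:
                raise ValueError(f"continuous factor {term.factor!r} missing from scheme")
            binning = scheme.continuous[term.factor]
            beta = float(params[term.factor])
            points[term.factor] = {
                lab: round_half_away(beta * (binning.w[lab] - binning.w_ref) / b)
                for lab in binning.labels
            }
            betas[term.factor] = {"__continuous__": beta}
            c += beta * (binning.w_ref - float(fit.covariate_means[term.factor]))
        else:
            pts, bts = {term.reference: 0}, {term.reference: 0.0}
            for cat in term.categories:
                if cat == term.reference:
                    continue
                col = f"{term.factor}[{cat}]"
                beta = float(params[col])
                pts[cat] = round_half_away(beta / b)
                bts[cat] = beta
                # W_iREF = 0 for indicators: reference profile has indicator 0
                c -= beta * float(fit.covariate_means[col])
            points[term.factor] = pts
            betas[term.factor] = bts
    return PointSystem(
        b=b,
        points=points,
        s0=dict(fit.baseline_survival),
        risk_constant=c,
        scheme=scheme,
        betas=betas,
    )


def total_score(categories: Mapping[str, object], system: PointSystem) -> int:
    return system.total_score(categories)


def risk_from_score(score, system: PointSystem, t: float):
    return system.risk(score, t)


def s0_from_anchor(b: float, points: float, risk_pct: float) -> float:
    """Baseline survival implied by one (score, risk%) anchor with c = 0.

    Solves 1 - S0 ** exp(b * P) = risk for S0; used to rebuild the
    points->risk map of a published system whose S0 and centering constant
    were not reported separately.
    """
    if not 0.0 < risk_pct < 100.0:
        raise ValueError("anchor risk must be strictly inside (0, 100)%")
    return float(np.exp(np.log1p(-risk_pct / 100.0) / np.exp(b * points)))


def build_risk_table(
    system: PointSystem,
    bins: Sequence[tuple[int, int]] | int | None = 3,
    horizons: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Predicted risk (%) per total-score bin at each horizon.

    ``bins`` is either an explicit list of (lo, hi) point totals, a bin
    width covering the system's score range, or None for one row per
    integer score. Each row reports the risk at the bin's lower and upper
    score, rounded to two decimals; risks increase with points and horizon.
    """
    lo, hi = system.score_range
    if bins is None:
        bin_list = [(p, p) for p in range(lo, hi + 1)]
    elif isinstance(bins, int):
        if bins < 1:
            raise ValueError("bin width must be >= 1")
        bin_list = [(p, min(p + bins - 1, hi)) for p in range(lo, hi + 1, bins)]
    else:
        bin_list = [(int(a), int(b_)) for a, b_ in bins]
    hs = tuple(horizons) if horizons is not None else system.horizons
    rows = []
    for blo, bhi in bin_list:
        row = {"points_lo": blo, "points_hi": bhi}
        for t in hs:
            row[f"r{t:g}_lo"] = round(100.0 * system.risk(blo, t), 2)
            row[f"r{t:g}_hi"] = round(100.0 * system.risk(bhi, t), 2)
        rows.append(row)
    return pd.DataFrame(rows)
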