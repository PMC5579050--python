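"""Point derivation, total scores and the points -> risk mapping."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pointrisk.model import TermSpec
from pointrisk.points import (
    PointSystem,
    build_point_system,
    build_risk_table,
    default_scheme,
    round_half_away,
    risk_from_score,
    s0_from_anchor,
    total_score,
)
from pointrisk.tables import ANCHOR_B, printed_point_system


@pytest.mark.parametrize(
    "x,expected",
    [(0.5, 1), (-0.5, -1), (1.35, 1), (2.5, 3), (-2.5, -3), (0.0, 0), (5.078, 5)],
)
def test_rounding_half_away_from_zero(x, expected):
    assert round_half_away(x) == expected


class _FakeFit:
    """Minimal stand-in carrying only what build_point_system reads."""

    def __init__(self, terms, params, means, s0):
        self.terms = terms
        self.params = pd.Series(params)
        self.covariate_means = pd.Series(means)
        self.baseline_survival = s0


def _fake_fit(betas=None, age_beta=0.02):
    terms = [
        TermSpec("age"),
        TermSpec("retinopathy", ("no", "yes")),
        TermSpec("bp_status", ("no_lt130", "yes_ge160")),
        TermSpec("dm_med", ("none", "oral")),
    ]
    betas = betas or {
        "age": age_beta,
        "retinopathy[yes]": 0.88,
        "bp_status[yes_ge160]": 1.65,
        "dm_med[oral]": -0.60,
    }
    means = {"age": 61.0, "retinopathy[yes]": 0.01, "bp_status[yes_ge160]": 0.08, "dm_med[oral]": 0.86}
    s0 = {3.0: 0.995, 5.0: 0.99, 8.0: 0.975}
    return _FakeFit(terms, betas, means, s0)


class TestBuild:
    def test_published_coefficients_reproduce_published_points(self):
        # with B pinned by the creatinine row (2.57 -> 29 points):
        sys_ = build_point_system(_fake_fit(), b_rule=ANCHOR_B)
        assert sys_.points["retinopathy"]["yes"] == 10
        assert sys_.points["bp_status"]["yes_ge160"] == 19
        assert sys_.points["dm_med"]["oral"] == -7
        assert sys_.points["retinopathy"]["no"] == 0  # reference scores zero

    def test_age_points_span_minus2_to_8(self):
        sys_ = build_point_system(_fake_fit(), b_rule="5x_age_beta")
        age_pts = sys_.points["age"]
        assert age_pts["30-34"] == -2 and age_pts["80-84"] == 8 and age_pts["40-44"] == 0

    def test_zero_beta_scores_zero_and_joint_rescale_invariance(self):
        fit = _fake_fit()
        fit.params["retinopathy[yes]"] = 0.0
        a = build_point_system(fit, b_rule=ANCHOR_B)
        assert a.points["retinopathy"]["yes"] == 0
        doubled = _fake_fit(
            betas={k: 2 * v for k, v in _fake_fit().params.items()}
        )
        b = build_point_system(doubled, b_rule=2 * ANCHOR_B)
        base = build_point_system(_fake_fit(), b_rule=ANCHOR_B)
        # doubling every beta and B together leaves all points unchanged
        assert {f: p for f, p in b.points.items() if f != "age"} == {
            f: p for f, p in base.points.items() if f != "age"
        }

    def test_nonpositive_b_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            build_point_system(_fake_fit(age_beta=-0.02), b_rule="5x_age_beta")

    def test_missing_age_term_under_default_rule(self):
        fit = _fake_fit()
        fit.terms = fit.terms[1:]
        fit.params = fit.params.drop("age")
        with pytest.raises(ValueError, match="age"):
            build_point_system(fit, b_rule="5x_age_beta")


class TestTotalScore:
    def test_all_reference_profile_scores_zero(self):
        sys_ = printed_point_system()
        refs = {
            "age": "40-44", "gender": "female", "onset_age": "lt45",
            "creatinine": "lt2", "hba1c_cv": "low", "sbp_cv": "low",
            "retinopathy": "no", "albuminuria": "no", "dm_med": "none",
            "bp_status": "no_lt130", "lipid_status": "no_lt200",
        }
        assert total_score(refs, sys_) == 0

    def test_published_score_range_is_minus16_to_97(self):
        assert printed_point_system().score_range == (-16, 97)

    def test_numeric_age_is_binned_for_scoring(self):
        sys_ = printed_point_system()
        refs = {
            "age": 83.0, "gender": "female", "onset_age": "lt45",
            "creatinine": "lt2", "hba1c_cv": "low", "sbp_cv": "low",
            "retinopathy": "no", "albuminuria": "no", "dm_med": "none",
            "bp_status": "no_lt130", "lipid_status": "no_lt200",
        }
        assert total_score(refs, sys_) == 8

    def test_unknown_category_and_missing_factor_rejected(self):
        sys_ = printed_point_system()
        with pytest.raises(KeyError, match="missing factor"):
            total_score({"age": "40-44"}, sys_)
        full = {f: list(p)[0] for f, p in sys_.points.items()}
        full["creatinine"] = "nope"
        with pytest.raises(KeyError, match="unknown category"):
            total_score(full, sys_)


class TestRiskMap:
    def test_certain_survival_gives_zero_risk(self):
        sys_ = PointSystem(b=0.1, points={"f": {"a": 0, "b": 5}}, s0={3.0: 1.0})
        assert risk_from_score(50, sys_, 3.0) == 0.0

    def test_centering_identity(self):
        # B*P + c = 0 -> risk is exactly 1 - S0(t)
        sys_ = PointSystem(
            b=0.1, points={"f": {"a": 0}}, s0={5.0: 0.95}, risk_constant=-0.5
        )
        assert risk_from_score(5, sys_, 5.0) == pytest.approx(0.05, abs=1e-12)

    def test_anchor_extrapolates_across_published_band(self):
        # calibrated at (20 -> 2.82%), the predicted 3y risk at P=50 must
        # fall within 2 points of the published 32.46-34.83 band
        s0 = s0_from_anchor(ANCHOR_B, 20, 2.82)
        sys_ = PointSystem(b=ANCHOR_B, points={"f": {"a": 0}}, s0={3.0: s0})
        p50 = 100 * risk_from_score(50, sys_, 3.0)
        assert 32.46 - 2 <= p50 <= 34.83 + 2

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(-16, 69))
    def test_strictly_increasing_in_points(self, p):
        # strict below the region where the risk saturates to 1.0 in floats
        sys_ = printed_point_system()
        for t in (3.0, 5.0, 8.0):
            assert sys_.risk(p + 1, t) > sys_.risk(p, t)
            assert sys_.risk(97, t) >= sys_.risk(p + 1, t)

    def test_unknown_horizon_rejected(self):
        sys_ = printed_point_system()
        with pytest.raises(KeyError, match="horizon"):
            sys_.risk(0, 4.0)


class TestRiskTable:
    def test_degenerate_single_bin(self):
        sys_ = printed_point_system()
        tab = build_risk_table(sys_, bins=[(10, 10)])
        assert len(tab) == 1
        assert tab.loc[0, "r3_lo"] == tab.loc[0, "r3_hi"]

    def test_monotone_over_points_and_horizons(self):
        tab = build_risk_table(printed_point_system(), bins=3)
        for edge in ("lo", "hi"):
            sub = tab[[f"r3_{edge}", f"r5_{edge}", f"r8_{edge}"]].to_numpy()
            assert (np.diff(sub, axis=1) >= 0).all()  # across horizons
            assert (np.diff(sub, axis=0) >= 0).all()  # down the rows

    def test_saturates_at_100_for_extreme_totals(self):
        tab = build_risk_table(printed_point_system(), bins=3)
        assert tab.iloc[-1]["r8_hi"] == 100.0

    def test_serialization_round_trip_bit_identical(self):
        sys_ = printed_point_system()
        clone = PointSystem.from_json(sys_.to_json())
        pd.testing.assert_frame_equal(
            build_risk_table(sys_, bins=3), build_risk_table(clone, bins=3)
        )
        assert clone.to_json() == sys_.to_json()


def test_fitted_points_match_generating_points():
    """Points from estimated coefficients agree with points from the
    generating coefficients to within one point for well-estimated
    categories.

    Uses an event-rich cohort (constant hazard 0.05/year) so that common
    categories are estimated precisely; categories whose coefficient SE
    exceeds a third of the point constant are too noisy for a one-point
    guarantee and are excluded."""
    from pointrisk.model import fit_cox
    from pointrisk.simulate import GeneratorConfig, default_betas, simulate_cohort

    coh = simulate_cohort(
        GeneratorConfig(n_subjects=20000, baseline_hazard=0.05, dropout_rate=0.0, seed=77)
    )
    fit = fit_cox(coh)
    b_true = 5 * 0.02
    fitted = build_point_system(fit, b_rule=b_true)
    truth = default_betas()
    checked = 0
    for factor, cats in fitted.points.items():
        if factor == "age":
            continue
        for cat, pts in cats.items():
            col = f"{factor}[{cat}]"
            if col not in truth or float(fit.bse[col]) > b_true / 3:
                continue
            expected = round_half_away(truth[col] / b_true)
            assert abs(pts - expected) <= 1, (col, pts, expected)
            checked += 1
    assert checked >= 5
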