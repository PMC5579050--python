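"""Cox fitting, model selection and the proportional-hazards probe."""

import numpy as np
import pandas as pd
import pytest

from pointrisk.model import (
    CoxPointModel,
    CoxPointResults,
    TermSpec,
    backward_select,
    collinearity_screen,
    default_terms,
    design_matrix,
    fit_cox,
    km_loglog_data,
    ph_check_by_censoring,
    univariable_screen,
)
from pointrisk.simulate import GeneratorConfig, simulate_cohort


def _one_factor_cohort(n, beta, prev=0.3, lam0=0.01, seed=0):
    cfg = GeneratorConfig(
        n_subjects=n,
        covariate_prevalences={"f": {"yes": prev}},
        true_betas={"f[yes]": beta},
        baseline_hazard=lam0,
        admin_censor_years=8.0,
        dropout_rate=0.0,
        seed=seed,
    )
    return simulate_cohort(cfg), TermSpec("f", ("ref", "yes"))


def _efron_loglik(beta, time, event, x):
    """Brute-force Efron partial log-likelihood for one covariate."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        deaths = (time == t) & (event == 1)
        risk = time >= t
        d = deaths.sum()
        sum_risk = np.exp(beta * x[risk]).sum()
        sum_dead = np.exp(beta * x[deaths]).sum()
        ll += beta * x[deaths].sum()
        for el in range(d):
            ll -= np.log(sum_risk - (el / d) * sum_dead)
    return ll


class TestFit:
    def test_exchangeable_groups_give_zero_coefficient(self):
        # identical event-time multisets per group: symmetry forces beta = 0
        df = pd.DataFrame(
            {
                "g": ["a"] * 4 + ["b"] * 4,
                "follow_time": [1.0, 2.0, 3.0, 4.0] * 2,
                "event": [1] * 8,
            }
        )
        res = fit_cox(df, [TermSpec("g", ("a", "b"))], horizons=(3.0,))
        assert abs(res.params.iloc[0]) < 1e-6

    def test_matches_brute_force_efron_grid(self):
        time = np.array([1.0, 1.0, 2.0, 3.0, 4.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1, 0, 1, 0, 1, 0, 0, 1])
        df = pd.DataFrame(
            {"f": np.where(x == 1, "yes", "ref"), "follow_time": time, "event": event}
        )
        res = fit_cox(df, [TermSpec("f", ("ref", "yes"))], horizons=(3.0,))
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [_efron_loglik(b, time, event, x) for b in grid]
        beta_grid = grid[int(np.argmax(lls))]
        assert res.params.iloc[0] == pytest.approx(beta_grid, abs=1e-3)

    def test_row_order_invariance(self, midsize_cohort, midsize_fit):
        shuffled = midsize_cohort.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = fit_cox(shuffled)
        pd.testing.assert_series_equal(midsize_fit.params, res2.params, atol=1e-8, rtol=0)

    def test_reference_relabeling_shifts_betas_consistently(self):
        coh, _ = _one_factor_cohort(3000, 0.8, seed=4)
        coh["f3"] = np.random.default_rng(0).choice(["a", "b", "c"], len(coh))
        t_a = TermSpec("f3", ("a", "b", "c"), reference="a")
        t_b = TermSpec("f3", ("a", "b", "c"), reference="b")
        ra = fit_cox(coh, [t_a], horizons=(5.0,))
        rb = fit_cox(coh, [t_b], horizons=(5.0,))
        # linear transform of coefficients ...
        assert rb.params["f3[c]"] == pytest.approx(
            ra.params["f3[c]"] - ra.params["f3[b]"], abs=1e-5
        )
        # ... and identical predicted risks
        pa = ra.predict_risk(coh, 5.0)
        pb = rb.predict_risk(coh, 5.0)
        assert np.allclose(pa, pb, atol=1e-8)

    def test_baseline_survival_monotone_and_loglik_improves(self, midsize_fit):
        s = midsize_fit.baseline_survival
        assert 0 < s[8.0] <= s[5.0] <= s[3.0] <= 1
        from pointrisk.model import _null_log_likelihood

        assert midsize_fit.log_likelihood >= _null_log_likelihood(midsize_fit)

    def test_risk_equation_centering_identity(self, midsize_cohort, midsize_fit):
        # a subject exactly at the covariate means has risk 1 - S0(t)
        X = design_matrix(midsize_cohort, midsize_fit.terms)
        lp = (X.mean() - midsize_fit.covariate_means) @ midsize_fit.params
        assert 1 - midsize_fit.baseline_survival[5.0] ** np.exp(lp) == pytest.approx(
            1 - midsize_fit.baseline_survival[5.0], abs=1e-12
        )

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"f": ["ref", "yes"], "follow_time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError, match="two events"):
            CoxPointModel(df, [TermSpec("f", ("ref", "yes"))])

    def test_zero_variance_column_rejected(self):
        df = pd.DataFrame(
            {"f": ["yes"] * 6, "follow_time": np.arange(1.0, 7.0), "event": [1] * 6}
        )
        with pytest.raises(ValueError, match="zero-variance"):
            CoxPointModel(df, [TermSpec("f", ("ref", "yes"))])

    def test_json_round_trip_preserves_predictions(self, midsize_cohort, midsize_fit):
        clone = CoxPointResults.from_json(midsize_fit.to_json())
        pd.testing.assert_series_equal(
            clone.predict_risk(midsize_cohort, 8.0),
            midsize_fit.predict_risk(midsize_cohort, 8.0),
        )

    def test_summary_reports_hazard_ratios(self, midsize_fit):
        s = midsize_fit.summary()
        assert {"coef", "se", "p", "hr"} <= set(s.columns)
        assert np.allclose(s["hr"], np.exp(s["coef"]))


class TestSelection:
    def test_alpha_one_retains_everything(self, midsize_cohort):
        retained, tab = univariable_screen(midsize_cohort, alpha=1.0)
        assert len(retained) == len(default_terms())
        assert (tab["p"] <= 1).all()

    def test_null_factor_usually_excluded_at_permissive_alpha(self):
        kept = 0
        n_reps = 400
        for rep in range(n_reps):
            coh, term = _one_factor_cohort(5000, 0.0, seed=1000 + rep)
            retained, _ = univariable_screen(coh, [term], alpha=0.25, horizons=(8.0,))
            kept += bool(retained)
        assert (n_reps - kept) / n_reps >= 0.70  # ~75% expected at alpha=0.25

    def test_strong_factor_always_retained(self):
        for rep in range(20):
            coh, term = _one_factor_cohort(5000, 1.0, prev=0.1, seed=2000 + rep)
            retained, _ = univariable_screen(coh, [term], alpha=0.25, horizons=(8.0,))
            assert retained

    def test_alpha_stay_one_keeps_full_model(self, midsize_cohort):
        sel = backward_select(midsize_cohort, alpha_stay=1.0)
        assert not sel.empty and len(sel.retained) == len(default_terms())

    def test_noise_factors_pruned_strong_factor_kept(self):
        cfg = GeneratorConfig(
            n_subjects=10000,
            covariate_prevalences={
                "strong": {"yes": 0.1},
                **{f"noise{i}": {"yes": 0.3} for i in range(4)},
            },
            true_betas={"strong[yes]": 1.0},
            baseline_hazard=0.01,
            dropout_rate=0.0,
            admin_censor_years=8.0,
            seed=6,
        )
        coh = simulate_cohort(cfg)
        terms = [TermSpec("strong", ("ref", "yes"))] + [
            TermSpec(f"noise{i}", ("ref", "yes")) for i in range(4)
        ]
        sel = backward_select(coh, terms, horizons=(8.0,))
        assert [t.factor for t in sel.retained] == ["strong"]

    def test_all_null_model_usually_empties(self):
        empties, retained_total = 0, 0
        for rep in range(10):
            cfg = GeneratorConfig(
                n_subjects=1000,
                covariate_prevalences={f"n{i}": {"yes": 0.4} for i in range(5)},
                true_betas={},
                baseline_hazard=0.02,
                dropout_rate=0.0,
                admin_censor_years=8.0,
                seed=3000 + rep,
            )
            coh = simulate_cohort(cfg)
            terms = [TermSpec(f"n{i}", ("ref", "yes")) for i in range(5)]
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                sel = backward_select(coh, terms, horizons=(8.0,))
            empties += sel.empty
            retained_total += len(sel.retained)
        assert empties >= 5
        assert retained_total / 10 <= 1.0


class TestPHCheck:
    def test_no_flags_under_proportional_hazards(self):
        coh = simulate_cohort(GeneratorConfig(n_subjects=20000, seed=8))
        report = ph_check_by_censoring(coh)
        assert not report["flagged"].any()

    def test_time_reversing_effect_is_flagged(self):
        # piecewise hazard: exposed group's log-hazard flips from +1.5 to
        # -1.5 after year 3; coefficients censored at 3y vs 8y must disagree
        rng = np.random.default_rng(5)
        n = 8000
        x = rng.random(n) < 0.5
        lam0, tau = 0.05, 3.0
        lam_early = np.where(x, lam0 * np.exp(1.5), lam0)
        lam_late = np.where(x, lam0 * np.exp(-1.5), lam0)
        e = rng.exponential(size=n)
        T = np.where(e < lam_early * tau, e / lam_early, tau + (e - lam_early * tau) / lam_late)
        df = pd.DataFrame(
            {
                "f": np.where(x, "yes", "ref"),
                "follow_time": np.minimum(T, 8.0),
                "event": (T <= 8.0).astype(int),
            }
        )
        report = ph_check_by_censoring(df, [TermSpec("f", ("ref", "yes"))])
        assert report.loc["f[yes]", "flagged"]

    def test_single_horizon_cannot_flag(self, midsize_cohort):
        report = ph_check_by_censoring(midsize_cohort, horizons=(8.0,))
        assert not report["flagged"].any()


def test_collinear_factors_flagged():
    coh, term = _one_factor_cohort(2000, 0.5, seed=9)
    coh["f2"] = coh["f"]
    terms = [term, TermSpec("f2", ("ref", "yes"))]
    diag = collinearity_screen(coh, terms)
    assert diag["flagged"].all()


def test_loglog_plot_data_monotone_per_stratum():
    coh, _ = _one_factor_cohort(2000, 0.8, seed=10)
    dat = km_loglog_data(coh, "f")
    for _, grp in dat.groupby("stratum"):
        assert grp["neg_log_s"].is_monotonic_increasing
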