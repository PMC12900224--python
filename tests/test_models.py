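"""Cox and logistic model fitting, covariate encoding, Kaplan-Meier curves
and the pooled multiple-imputation analysis wrapper."""

import numpy as np
import pandas as pd
import pytest

from dcdliver.models import (
    ModelSpec,
    Term,
    encode_covariates,
    fit_cox,
    fit_logistic,
    km_curve,
    run_mi_analysis,
)
from dcdliver.splines import SplineSpec


def _binary_spec(*terms):
    return ModelSpec(name="m", outcome_type="binary", outcome="y", terms=terms)


class TestEncodeCovariates:
    def test_log2_definition(self):
        df = pd.DataFrame({"waitlist_days": [10.0], "y": [1]})
        X, groups = encode_covariates(df, _binary_spec(Term("waitlist_days", "log2")))
        assert X.iloc[0, 0] == pytest.approx(np.log2(10.0), abs=1e-4)

    def test_doubling_changes_encoded_value_by_one(self):
        df = pd.DataFrame({"v": [5.0, 10.0, 20.0], "y": [0, 1, 0]})
        X, _ = encode_covariates(df, _binary_spec(Term("v", "log2")))
        assert np.allclose(np.diff(X["log2_v"]), 1.0)

    def test_nonpositive_log2_is_hard_error(self):
        df = pd.DataFrame({"v": [0.0, 4.0], "y": [0, 1]})
        with pytest.raises(ValueError, match="log2_offset"):
            encode_covariates(df, _binary_spec(Term("v", "log2")))

    def test_log2_offset_option(self):
        df = pd.DataFrame({"v": [0.0, 3.0], "y": [0, 1]})
        X, _ = encode_covariates(df, _binary_spec(Term("v", "log2", log2_offset=1.0)))
        assert X.iloc[0, 0] == 0.0
        assert X.iloc[1, 0] == 2.0

    def test_linear_scale_divides(self):
        df = pd.DataFrame({"age": [60.0], "y": [1]})
        X, _ = encode_covariates(df, _binary_spec(Term("age", scale=10.0)))
        assert X.iloc[0, 0] == 6.0

    def test_categorical_reference_dropped(self):
        df = pd.DataFrame({"g": ["a", "b", "c", "a"], "y": [0, 1, 0, 1]})
        X, groups = encode_covariates(
            df, _binary_spec(Term("g", "categorical", reference="a"))
        )
        assert sorted(X.columns) == ["g_b", "g_c"]
        assert groups["g"] == ["g_b", "g_c"]

    def test_missing_reference_level_rejected(self):
        df = pd.DataFrame({"g": ["a", "b"], "y": [0, 1]})
        with pytest.raises(ValueError, match="reference"):
            encode_covariates(df, _binary_spec(Term("g", "categorical", reference="z")))

    def test_binary_flag_by_spline_interaction_has_three_columns(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"x": rng.uniform(0, 100, 200), "flag": rng.integers(0, 2, 200), "y": 0}
        )
        spline = SplineSpec("x", knots=(5.0, 35.0, 65.0, 95.0))
        spec = ModelSpec(
            name="m",
            outcome_type="binary",
            outcome="y",
            terms=(Term("x", "rcs", spline=spline), Term("flag")),
            interactions=(("flag", "x"),),
        )
        X, groups = encode_covariates(df, spec)
        assert len(groups["flag:x"]) == 3

    def test_duplicate_covariate_rejected(self):
        with pytest.raises(ValueError, match="once"):
            _binary_spec(Term("a"), Term("a"))


def _two_group_survival(rng, n=5000, hr=2.0, lam=0.01):
    x = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (lam * hr**x))
    return pd.DataFrame({"x": x.astype(float), "time": t, "event": 1})


class TestFitCox:
    spec = ModelSpec(
        name="cox",
        outcome_type="time-to-event",
        duration_col="time",
        event_col="event",
        terms=(Term("x"),),
    )

    def test_two_group_hazard_ratio_recovered(self, rng):
        df = _two_group_survival(rng)
        fit = fit_cox(df, self.spec)
        hr = float(np.exp(fit.params["x"]))
        assert 1.85 <= hr <= 2.16

    def test_no_events_rejected(self, rng):
        df = _two_group_survival(rng, n=50).assign(event=0)
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, self.spec)

    def test_constant_covariate_named(self, rng):
        df = _two_group_survival(rng, n=50).assign(x=1.0)
        with pytest.raises(ValueError, match="x"):
            fit_cox(df, self.spec)

    def test_invariant_to_time_shift(self, rng):
        df = _two_group_survival(rng, n=800)
        a = fit_cox(df, self.spec)
        b = fit_cox(df.assign(time=df["time"] + 1000.0), self.spec)
        assert a.params["x"] == pytest.approx(b.params["x"], abs=1e-8)

    def test_horizon_truncation_reduces_events(self, rng):
        df = _two_group_survival(rng, n=500)
        full = fit_cox(df, self.spec)
        from dataclasses import replace

        short = fit_cox(df, replace(self.spec, horizon_days=20.0))
        assert short.n_events < full.n_events


class TestFitLogistic:
    def test_intercept_only_balanced_outcome(self):
        df = pd.DataFrame({"y": [0, 1] * 100})
        spec = ModelSpec(name="m", outcome_type="binary", outcome="y", terms=())
        fit = fit_logistic(df, spec)
        assert fit.params["const"] == pytest.approx(0.0, abs=1e-8)

    def test_known_slope_recovered_within_three_se(self, rng):
        n = 10_000
        x = rng.normal(size=n)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-0.7 * x))).astype(int)
        fit = fit_logistic(pd.DataFrame({"x": x, "y": y}), _binary_spec(Term("x")))
        se = float(np.sqrt(fit.cov.loc["x", "x"]))
        assert abs(fit.params["x"] - 0.7) < 3 * se

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1, 1]})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(df, _binary_spec(Term("x")))

    def test_nonbinary_outcome_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1, 2]})
        with pytest.raises(ValueError, match="0/1"):
            fit_logistic(df, _binary_spec(Term("x")))

    def test_mean_fitted_probability_equals_observed_rate(self, rng):
        # maximum-likelihood identity with an intercept in the model
        n = 500
        x = rng.normal(size=n)
        y = (rng.random(n) < 1.0 / (1.0 + np.exp(-(0.3 + 0.5 * x)))).astype(int)
        df = pd.DataFrame({"x": x, "y": y})
        fit = fit_logistic(df, _binary_spec(Term("x")))
        import statsmodels.api as sm
        from scipy.special import expit

        X = sm.add_constant(df[["x"]])
        p = expit(X.to_numpy() @ fit.params.to_numpy())
        assert p.mean() == pytest.approx(y.mean(), abs=1e-8)

    def test_separation_flagged(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)].astype(float),
                           "y": np.r_[np.zeros(20), np.ones(20)].astype(int)})
        fit = fit_logistic(df, _binary_spec(Term("x")))
        assert any("separation" in f for f in fit.flags)


class TestKmCurve:
    def test_product_limit_by_hand(self):
        km = km_curve(np.array([1.0, 2.0, 3.0, 4.0]), np.ones(4))
        s_at_2 = km.loc[km["time"] == 2.0, "survival"].iloc[0]
        assert s_at_2 == pytest.approx(0.5)

    def test_all_censored_survival_stays_one(self):
        km = km_curve(np.array([1.0, 5.0, 9.0]), np.zeros(3))
        assert (km["survival"] == 1.0).all()

    def test_matches_brute_force_product_limit(self, rng):
        t = np.round(rng.exponential(10.0, 60), 1)
        e = (rng.random(60) < 0.6).astype(int)
        km = km_curve(t, e)
        # independent product-limit enumeration over distinct event times
        for t0 in np.unique(t[e == 1]):
            s = 1.0
            for ti in np.unique(t[e == 1]):
                if ti <= t0:
                    d = ((t == ti) & (e == 1)).sum()
                    n_at = (t >= ti).sum()
                    s *= 1 - d / n_at
            got = km.loc[km["time"] == t0, "survival"].iloc[0]
            assert got == pytest.approx(s, abs=1e-10)

    def test_groups_and_at_risk_counts(self, rng):
        t = rng.exponential(10.0, 100)
        e = np.ones(100)
        g = np.repeat(["a", "b"], 50)
        km = km_curve(t, e, g, at_risk_times=np.array([0.0]))
        assert set(km["group"]) == {"a", "b"}
        at0 = km.loc[(km["time"] == 0.0), "n_at_risk"]
        assert (at0 == 50).all()


class TestRunMiAnalysis:
    def test_zero_missingness_equals_single_fit(self, rng):
        df = _two_group_survival(rng, n=600)
        spec = TestFitCox.spec
        single = fit_cox(df, spec)
        mi = run_mi_analysis([df.copy() for _ in range(5)], spec)
        assert mi.pooled.beta[0] == pytest.approx(single.params["x"], abs=1e-12)
        assert mi.pooled.cov[0, 0] == pytest.approx(
            float(single.cov.iloc[0, 0]), abs=1e-12
        )

    def test_failing_dataset_reported_by_index(self, rng):
        df = _two_group_survival(rng, n=200)
        bad = df.assign(event=0)
        with pytest.raises(RuntimeError, match="dataset 1"):
            run_mi_analysis([df, bad], TestFitCox.spec)

    def test_spline_wald_and_curve_produced(self, rng):
        n = 1200
        ttd = np.exp(rng.normal(np.log(13.0), 0.47, n))
        lp = 0.5 * np.clip((8.0 - ttd) / 8.0, 0, None)
        t = rng.exponential(1.0 / (0.002 * np.exp(lp)))
        df = pd.DataFrame({"ttd_min": ttd, "time": t, "event": 1})
        spec = ModelSpec(
            name="m",
            outcome_type="time-to-event",
            duration_col="time",
            event_col="event",
            terms=(Term("ttd_min", "rcs"),),
            curve_terms=("ttd_min",),
        )
        mi = run_mi_analysis([df], spec)
        assert "ttd_min" in mi.wald
        curve = mi.curves["ttd_min"]
        assert np.all(curve.ratio > 0)
        assert np.all(curve.lo <= curve.ratio) and np.all(curve.ratio <= curve.hi)


def test_effect_curve_recovery_improves_with_sample_size():
    """Integrated squared error between the fitted and true log-hazard
    curves over the central TTD range shrinks as n grows."""
    from dcdliver.registry import GeneratorConfig, generate_registry

    spec = ModelSpec(
        name="m",
        outcome_type="time-to-event",
        duration_col="graft_time_days",
        event_col="graft_event",
        terms=(Term("ttd_min", "rcs"),),
        curve_terms=("ttd_min",),
    )

    def ise(n, seed):
        config = GeneratorConfig(
            n_donors=n, seed=seed, nrp_fraction=0.0, uncontrolled_fraction=0.0,
            censoring_rate=0.0, missingness={}, recipient_log_hr={},
        )
        donors, tx, truth = generate_registry(config)
        tx = tx.merge(donors[["donor_id", "ttd_min"]], on="donor_id")
        mi = run_mi_analysis([tx], spec)
        ttd = tx["ttd_min"].to_numpy()
        grid = np.linspace(np.percentile(ttd, 5), np.percentile(ttd, 95), 60)
        x_ref = mi.spec.term("ttd_min").spline.reference
        true_lhr = config.graft_hazard.log_hr(grid) - config.graft_hazard.log_hr(
            np.array([x_ref])
        )
        idx = mi.pooled.term_index(mi.pooled.groups["ttd_min"])
        from dcdliver.splines import effect_curve

        curve = effect_curve(
            mi.pooled.beta, mi.pooled.cov, idx, mi.spec.term("ttd_min").spline, grid
        )
        return float(np.trapezoid((np.log(curve.ratio) - true_lhr) ** 2, grid))

    seeds = [101, 202, 303]
    small = np.mean([ise(1500, s) for s in seeds])
    large = np.mean([ise(9000, s) for s in seeds])
    assert large < small
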