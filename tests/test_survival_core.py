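import numpy as np
import pandas as pd
import pytest

from coxsens.exceptions import ConvergenceError, ValidationError
from coxsens.io_core import SurvivalSample
from coxsens.survival_core import (
    CoxFit, StepFunction, breslow_baseline_survivor, censoring_survivor, fit_reduced_cox,
)


def _lifelines_fit(sample, covariates=()):
    from lifelines import CoxPHFitter
    df = sample.to_frame()
    cph = CoxPHFitter()
    cph.fit(df[["time", "event", "exposure", *covariates]], "time", "event")
    return cph


class TestFit:
    def test_matches_lifelines(self, random_sample):
        """Coefficients, SEs and log-PL agree with an independent implementation."""
        fit = fit_reduced_cox(random_sample, ["z1", "z2"])
        cph = _lifelines_fit(random_sample, ("z1", "z2"))
        np.testing.assert_allclose(fit.coefficients,
                                   cph.params_[["exposure", "z1", "z2"]].to_numpy(),
                                   atol=1e-5)
        np.testing.assert_allclose(fit.se,
                                   cph.standard_errors_[["exposure", "z1", "z2"]].to_numpy(),
                                   atol=1e-4)
        assert fit.score_norm < 1e-8

    def test_consistency_under_correct_model(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1.0, n) / np.exp(np.log(2) * x)
        s = SurvivalSample(time=t, event=np.ones(n, int), exposure=x)
        fit = fit_reduced_cox(s)
        assert abs(fit.coefficients[0] - np.log(2)) < 3 * fit.se[0]

    def test_separation_detected(self):
        s = SurvivalSample(time=[1.0, 2.0], event=[1, 1], exposure=[1.0, 0.0])
        with pytest.raises(ConvergenceError, match="separation|monotone"):
            fit_reduced_cox(s)

    def test_constant_exposure_rank_deficient(self):
        s = SurvivalSample(time=[1.0, 2.0, 3.0], event=[1, 1, 0], exposure=[1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="rank"):
            fit_reduced_cox(s)

    def test_partial_likelihood_is_maximum(self, random_sample):
        """PL at the optimum beats 100 random perturbations of norm 0.1."""
        fit = fit_reduced_cox(random_sample, ["z1", "z2"])
        # reuse the internal objective through a second fit at perturbed starts
        from coxsens.survival_core import _design_matrix, _risk_sums
        names, X = _design_matrix(random_sample, ["z1", "z2"])
        order = np.argsort(random_sample.time, kind="stable")
        t, d, Xs = random_sample.time[order], random_sample.event[order].astype(bool), X[order]
        uniq, first = np.unique(t, return_index=True)
        ev_idx = np.searchsorted(uniq, t[d])
        d_u = np.bincount(ev_idx, minlength=uniq.size).astype(float)
        has = d_u > 0

        def pl(b):
            s0, _, _ = _risk_sums(order, Xs @ b, Xs)
            return np.sum(Xs[d] @ b) - np.sum(d_u[has] * np.log(s0[first][has]))

        best = pl(fit.coefficients)
        rng = np.random.default_rng(0)
        for _ in range(100):
            u = rng.standard_normal(3)
            u *= 0.1 / np.linalg.norm(u)
            assert pl(fit.coefficients + u) <= best

    def test_wald_coverage_correctly_specified(self):
        """95% Wald CIs cover the truth 92-98% of the time when gamma = 0."""
        rng = np.random.default_rng(11)
        beta, hits = np.log(2), 0
        reps, n = 500, 150
        for _ in range(reps):
            x = (rng.random(n) < 0.5).astype(float)
            t = rng.exponential(1.0, n) / np.exp(beta * x)
            c = rng.uniform(0, 2.2, n)
            s = SurvivalSample(np.minimum(t, c), (t <= c).astype(int), x)
            fit = fit_reduced_cox(s)
            lo = fit.coefficients[0] - 1.96 * fit.se[0]
            hi = fit.coefficients[0] + 1.96 * fit.se[0]
            hits += lo <= beta <= hi
        assert 0.92 <= hits / reps <= 0.98


class TestBreslow:
    def test_hand_computed_increments(self):
        s = SurvivalSample(time=[1.0, 2.0, 3.0], event=[1, 1, 1], exposure=[0.0, 1.0, 0.0])
        fit = CoxFit(coefficients=np.zeros(1), covariance=np.eye(1), names=["exposure"],
                     n=3, n_events=3, log_partial_likelihood=0.0, score_norm=0.0, iterations=0)
        S0 = breslow_baseline_survivor(fit, s)
        np.testing.assert_allclose(S0.knots, [1.0, 2.0, 3.0])
        np.testing.assert_allclose(-np.log(S0.values), np.cumsum([1 / 3, 1 / 2, 1 / 1]))
        assert S0(0.0) == 1.0
        assert S0(3.5) == pytest.approx(np.exp(-11 / 6))

    def test_single_event_increment(self):
        n = 8
        s = SurvivalSample(time=[1.0] + [2.0] * (n - 1), event=[1] + [0] * (n - 1),
                           exposure=[0.0, 1.0] * (n // 2))
        fit = CoxFit(coefficients=np.zeros(1), covariance=np.eye(1), names=["exposure"],
                     n=n, n_events=1, log_partial_likelihood=0.0, score_norm=0.0, iterations=0)
        S0 = breslow_baseline_survivor(fit, s)
        assert S0.values[0] == pytest.approx(np.exp(-1 / n))

    def test_matches_nelson_aalen_at_null(self):
        """With beta = 0 the Breslow survivor equals exp(-Nelson-Aalen)."""
        from lifelines import NelsonAalenFitter
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 60
            t = rng.exponential(1.0, n)
            c = rng.uniform(0, 2, n)
            s = SurvivalSample(np.minimum(t, c), (t <= c).astype(int),
                               (rng.random(n) < 0.5).astype(float))
            fit = CoxFit(coefficients=np.zeros(1), covariance=np.eye(1), names=["exposure"],
                         n=n, n_events=s.n_events, log_partial_likelihood=0.0,
                         score_norm=0.0, iterations=0)
            S0 = breslow_baseline_survivor(fit, s)
            naf = NelsonAalenFitter()
            naf.fit(s.time, s.event)
            grid = np.linspace(0.01, s.time.max(), 23)
            na = naf.cumulative_hazard_at_times(grid).to_numpy()
            np.testing.assert_allclose(np.asarray(S0(grid)), np.exp(-na), atol=1e-10)

    def test_mismatched_fit_sample(self, random_sample):
        fit = fit_reduced_cox(random_sample)
        smaller = SurvivalSample(random_sample.time[:100], random_sample.event[:100],
                                 random_sample.exposure[:100])
        with pytest.raises(ValidationError):
            breslow_baseline_survivor(fit, smaller)

    def test_survivor_shape_invariants(self, random_sample, medium_dataset):
        for s in (random_sample, medium_dataset):
            fit = fit_reduced_cox(s)
            S0 = breslow_baseline_survivor(fit, s)
            assert S0.is_survivor()
            G = censoring_survivor(s, mode="pooled")
            assert G.is_survivor()


class TestCensoringSurvivor:
    def test_no_censoring_constant_one(self):
        s = SurvivalSample(time=[1.0, 2.0, 3.0], event=[1, 1, 1], exposure=[0, 1, 0])
        G = censoring_survivor(s, mode="pooled")
        assert G(0.5) == 1.0 and G(10.0) == 1.0

    def test_pooled_matches_reverse_kaplan_meier(self):
        """exp(-reverse Nelson-Aalen) tracks the reverse Kaplan-Meier curve.

        The two estimators differ by O(sum (d_i/n_i)^2), so agreement is
        asserted within a small tolerance rather than exactly.
        """
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(8)
        for _ in range(20):
            n = 250
            t = rng.exponential(1.0, n)
            c = rng.uniform(0, 2, n)
            s = SurvivalSample(np.minimum(t, c), (t <= c).astype(int),
                               (rng.random(n) < 0.5).astype(float))
            G = censoring_survivor(s, mode="pooled")
            kmf = KaplanMeierFitter()
            kmf.fit(s.time, 1 - s.event)
            grid = np.quantile(s.time, np.linspace(0.05, 0.9, 15))
            km = kmf.survival_function_at_times(grid).to_numpy()
            np.testing.assert_allclose(np.asarray(G(grid)), km, atol=0.02)

    def test_by_exposure_ordering(self):
        """Arm censored earlier has the lower censoring survivor at late times."""
        rng = np.random.default_rng(4)
        n = 5000
        x = np.repeat([1.0, 0.0], n // 2)
        t = rng.exponential(2.0, n)
        c = np.where(x == 1, rng.uniform(0, 1, n), rng.uniform(0, 4, n))
        s = SurvivalSample(np.minimum(t, c), (t <= c).astype(int), x)
        G = censoring_survivor(s, mode="by-exposure")
        for tt in (0.5, 0.8):
            assert G[1.0](tt) <= G[0.0](tt)

    def test_auto_mode_binary_is_by_exposure(self, medium_dataset):
        assert isinstance(censoring_survivor(medium_dataset), dict)


class TestStepFunction:
    def test_right_continuity_and_left_limits(self):
        f = StepFunction(knots=[1.0, 2.0], values=[0.5, 0.25], value_before=1.0)
        assert f(0.999) == 1.0 and f(1.0) == 0.5 and f(1.5) == 0.5 and f(2.0) == 0.25
        assert f.left_limit(1.0) == 1.0 and f.left_limit(2.0) == 0.5

    def test_validation(self):
        with pytest.raises(ValidationError):
            StepFunction(knots=[2.0, 1.0], values=[0.5, 0.2])
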