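import numpy as np
import pytest
from dataclasses import replace

from coxsens.bias_engine import (
    BinaryExposure, ExponentialCensoring, NoCensoring, NormalExposure,
    ScenarioSpec, UniformCensoring, binary_exposure_beta_star, nocensor_beta_star,
    lin_formula_correction, marginal_hazard_ratio, rare_event_relation,
    scenario_from_dict, score_limit, solve_beta_star, taylor_beta_star,
)
from coxsens.confounder_models import (
    BinaryConfounder, NormalConfounder, SensitivityParams, UniformConfounder,
)
from coxsens.exceptions import ValidationError
from coxsens.io_core import SurvivalSample
from coxsens.simulation import calibrate_censoring, generate_dataset
from coxsens.survival_core import fit_reduced_cox


def _random_scenario(rng, censoring=False):
    p1, p0 = rng.uniform(0.1, 0.9, 2)
    sc = ScenarioSpec(exposure=BinaryExposure(rng.uniform(0.2, 0.8)),
                      confounder=BinaryConfounder(p1, p0),
                      gamma=rng.uniform(-2, 2), beta=rng.uniform(-1, 1),
                      baseline_rate=rng.uniform(0.3, 2.0))
    if censoring:
        sc = replace(sc, censoring=UniformCensoring(rng.uniform(0.5, 3.0)))
    return sc


class TestScoreLimit:
    def test_vanishes_at_truth_when_correctly_specified(self, balanced_nocensor_scenario):
        sc = replace(balanced_nocensor_scenario, gamma=0.0)
        g = score_limit([sc.beta], sc)
        assert abs(g[0]) < 1e-12

    def test_strictly_decreasing_in_beta_star(self, balanced_nocensor_scenario):
        sc = balanced_nocensor_scenario
        grid = np.linspace(sc.beta - 3, sc.beta + 3, 20)
        vals = [float(score_limit([b], sc)[0]) for b in grid]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_root_matches_large_sample_mle(self, confounded_scenario):
        """The score-limit root agrees with the reduced MLE on a large dataset."""
        res = solve_beta_star(confounded_scenario)
        sample = generate_dataset(confounded_scenario, 200_000, 99)
        fit = fit_reduced_cox(sample)
        assert abs(res.scalar - fit.coefficients[0]) < 3 * fit.se[0]


class TestSolve:
    def test_gamma_zero_identity(self, confounded_scenario):
        sc = replace(confounded_scenario, gamma=0.0)
        for op in (solve_beta_star, binary_exposure_beta_star, taylor_beta_star):
            res = op(sc)
            assert res.bias[0] == pytest.approx(0.0, abs=1e-10)
        res = rare_event_relation(sc.beta, sc)
        assert res.bias[0] == 0.0

    def test_attenuation_balanced_covariate(self, balanced_nocensor_scenario):
        """Omitting a balanced covariate attenuates a positive effect toward 0."""
        res = solve_beta_star(balanced_nocensor_scenario)
        assert 0.0 < res.scalar < balanced_nocensor_scenario.beta

    def test_null_preserved_exactly(self):
        sc = ScenarioSpec(exposure=BinaryExposure(0.5), confounder=BinaryConfounder(0.5, 0.5),
                          gamma=1.5, beta=0.0, baseline_rate=1.0)
        assert abs(solve_beta_star(sc).scalar) < 1e-10

    def test_finite_limits_as_gamma_grows(self, balanced_nocensor_scenario):
        b10 = binary_exposure_beta_star(replace(balanced_nocensor_scenario, gamma=10.0)).scalar
        b12 = binary_exposure_beta_star(replace(balanced_nocensor_scenario, gamma=12.0)).scalar
        assert abs(b12 - b10) < 0.01

    def test_confounding_direction(self, balanced_nocensor_scenario):
        base = solve_beta_star(balanced_nocensor_scenario).scalar
        up = solve_beta_star(replace(balanced_nocensor_scenario,
                                     confounder=BinaryConfounder(0.7, 0.3))).scalar
        dn = solve_beta_star(replace(balanced_nocensor_scenario,
                                     confounder=BinaryConfounder(0.3, 0.7))).scalar
        assert up > base > dn


class TestCrossPaths:
    @pytest.mark.parametrize("gamma", [-2.0, 1.0, 3.0])
    @pytest.mark.parametrize("conf", [(0.9, 0.1), (0.5, 0.5)])
    def test_binary_path_equals_general_solver_censored(self, gamma, conf):
        sc = ScenarioSpec(exposure=BinaryExposure(0.5), confounder=BinaryConfounder(*conf),
                          gamma=gamma, beta=1.0, baseline_rate=0.57,
                          censoring=UniformCensoring(1.0))
        assert binary_exposure_beta_star(sc).scalar == pytest.approx(
            solve_beta_star(sc).scalar, abs=1e-5)

    def test_binary_path_normal_confounder(self):
        sc = ScenarioSpec(exposure=BinaryExposure(0.5),
                          confounder=NormalConfounder(0.0, 0.5, 1.0),
                          gamma=1.0, beta=0.5, baseline_rate=1.0,
                          censoring=ExponentialCensoring(0.7))
        assert binary_exposure_beta_star(sc).scalar == pytest.approx(
            solve_beta_star(sc).scalar, abs=1e-5)

    def test_nocensor_path_equals_general_solver(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            sc = _random_scenario(rng)
            assert nocensor_beta_star(sc).scalar == pytest.approx(
                solve_beta_star(sc).scalar, abs=1e-6)

    def test_nocensor_lambda0_invariance(self):
        vals = [nocensor_beta_star(
            ScenarioSpec(exposure=BinaryExposure(0.5), confounder=BinaryConfounder(0.8, 0.2),
                         gamma=1.5, beta=np.log(2), baseline_rate=lam)).scalar
            for lam in (0.1, 1.0, 10.0)]
        assert max(vals) - min(vals) < 1e-9

    def test_nocensor_requires_no_censoring(self, confounded_scenario):
        with pytest.raises(ValidationError):
            nocensor_beta_star(confounded_scenario)

    def test_binary_path_requires_binary_exposure(self):
        sc = ScenarioSpec(exposure=NormalExposure(0, 1), confounder=BinaryConfounder(0.5, 0.5),
                          gamma=1.0, beta=0.3)
        with pytest.raises(ValidationError):
            binary_exposure_beta_star(sc)


class TestTaylor:
    def test_error_grows_with_gamma(self, confounded_scenario):
        errs = []
        for g in (0.25, 2.0):
            sc = replace(confounded_scenario, gamma=g)
            errs.append(abs(taylor_beta_star(sc).scalar - solve_beta_star(sc).scalar))
        assert errs[0] < errs[1]

    def test_small_gamma_agreement(self):
        rng = np.random.default_rng(123)
        for _ in range(10):
            sc = replace(_random_scenario(rng, censoring=True), gamma=0.1)
            assert abs(taylor_beta_star(sc).scalar - solve_beta_star(sc).scalar) < 0.01


class TestRareEvent:
    def test_balanced_covariate_no_correction(self):
        sc = ScenarioSpec(exposure=BinaryExposure(0.4), confounder=BinaryConfounder(0.6, 0.6),
                          gamma=2.0, beta=0.8)
        assert rare_event_relation(sc.beta, sc).scalar == pytest.approx(0.8, abs=1e-12)

    def test_lin_correction_inverts_exactly(self):
        params = SensitivityParams(1.3, BinaryConfounder(0.2, 0.7))
        sc = ScenarioSpec(exposure=BinaryExposure(0.5), confounder=params.confounder,
                          gamma=params.gamma, beta=0.4)
        bstar = rare_event_relation(0.4, sc).scalar
        assert lin_formula_correction(bstar, params) == pytest.approx(0.4, abs=1e-12)

    def test_agrees_with_general_solver_under_heavy_censoring(self):
        """At ~95% censoring the rare-event relation matches the full score root."""
        sc = ScenarioSpec(exposure=BinaryExposure(0.5), confounder=UniformConfounder(0, 1),
                          gamma=1.0, beta=np.log(2), baseline_rate=1.0)
        sc = calibrate_censoring(sc, 0.95, solve_for="uniform_theta")["scenario"]
        assert abs(rare_event_relation(sc.beta, sc).scalar - solve_beta_star(sc).scalar) < 0.02

    def test_heavy_censoring_simulation_oracle(self):
        """Rare-event beta* tracks the mean reduced MLE when ~90% are censored."""
        sc = ScenarioSpec(exposure=BinaryExposure(0.5), confounder=UniformConfounder(0, 1),
                          gamma=1.0, beta=np.log(2), baseline_rate=1.0)
        sc = calibrate_censoring(sc, 0.90, solve_for="uniform_theta")["scenario"]
        target = rare_event_relation(sc.beta, sc).scalar
        rng = np.random.default_rng(31)
        ests = []
        for r in range(120):
            fit = fit_reduced_cox(generate_dataset(sc, 5000, rng))
            ests.append(fit.coefficients[0])
        se = np.std(ests) / np.sqrt(len(ests))
        assert abs(np.mean(ests) - target) < max(0.02, 3 * se)


class TestMarginalHazardRatio:
    def test_gamma_zero_constant(self, balanced_nocensor_scenario):
        sc = replace(balanced_nocensor_scenario, gamma=0.0)
        for t in (0.01, 1.0, 5.0):
            assert marginal_hazard_ratio(sc, t) == pytest.approx(np.exp(sc.beta), rel=1e-10)

    def test_nonproportional_when_confounder_omitted(self, balanced_nocensor_scenario):
        early = marginal_hazard_ratio(balanced_nocensor_scenario, 0.01)
        late = marginal_hazard_ratio(balanced_nocensor_scenario, 5.0)
        assert abs(early - late) > 1e-3

    def test_small_t_limit_is_mgf_ratio(self, confounded_scenario):
        sc = confounded_scenario
        m = sc.confounder.mgf
        want = np.exp(sc.beta) * m(sc.gamma, 1.0) / m(sc.gamma, 0.0)
        assert marginal_hazard_ratio(sc, 1e-6) == pytest.approx(want, rel=1e-4)


class TestCensoringEffect:
    def test_bias_nonmonotone_in_censoring(self):
        """|bias| peaks near 50% censoring and falls again toward 90%."""
        base = ScenarioSpec(exposure=BinaryExposure(0.5), confounder=BinaryConfounder(0.5, 0.5),
                            gamma=4.0, beta=1.0, baseline_rate=1.0)
        biases = {}
        for frac in (0.0, 0.5, 0.9):
            sc = (base if frac == 0.0 else
                  calibrate_censoring(base, frac, solve_for="uniform_theta_by_arm")["scenario"])
            biases[frac] = abs(binary_exposure_beta_star(sc).bias[0])
        assert biases[0.5] > biases[0.0]
        assert biases[0.5] > biases[0.9]


def test_scenario_from_dict_round_trip():
    sc = scenario_from_dict({
        "exposure": {"kind": "binary", "p": 0.4},
        "confounder": {"kind": "binary", "p1": 0.7, "p0": 0.2},
        "gamma": 1.5, "beta": 0.3, "baseline_rate": 0.8,
        "censoring": {"kind": "uniform", "theta": 2.0},
    })
    assert sc.exposure.p == 0.4 and sc.gamma == 1.5
    assert isinstance(sc.censoring, UniformCensoring)


def test_vector_scenario_with_measured_covariate():
    """Score system with a measured covariate: gamma=0 keeps both coordinates."""
    sc = ScenarioSpec(exposure=BinaryExposure(0.5), confounder=BinaryConfounder(0.5, 0.5),
                      gamma=0.0, beta=0.7, baseline_rate=1.0,
                      covariates=(("z", BinaryExposure(0.3), 0.4),))
    res = solve_beta_star(sc)
    np.testing.assert_allclose(res.beta_star, [0.7, 0.4], atol=1e-9)
    # with gamma > 0 the exposure coordinate attenuates
    res2 = solve_beta_star(replace(sc, gamma=1.5))
    assert res2.beta_star[0] < 0.7
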