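"""Asymptotic relation between the true and reduced-model Cox coefficients.

Model: the true hazard is ``lambda0(t) exp(beta' x + gamma c)`` but ``c`` is
unobserved, so the fitted ("reduced") model is ``lambda0*(t) exp(beta*' x)``.
As n grows, the reduced-model MLE converges to the root ``beta*`` of the
limiting average partial-likelihood score.  Writing ``v = Lambda0(t)`` for
the baseline cumulative hazard scale, ``eta = beta'x + gamma c`` for the true
log relative risk, ``G(t|x)`` for the censoring survivor, and ``E`` for the
expectation over the joint law of (X, C), the limit of the score for fitted
coordinate j is

    g_j(b) = Int_0^inf E[ (u_j - pi_j(b, v)) e^eta exp(-v e^eta) G(t(v)|x) ] dv

    pi_j(b, v) = E[ u_j e^{b'u} exp(-v e^eta) G(t(v)|x) ]
                 / E[ e^{b'u} exp(-v e^eta) G(t(v)|x) ]

where ``u`` collects the fitted covariates (exposure first).  The integrand
is the "event-weighted" covariate residual: ``e^eta exp(-v e^eta) G`` is the
density of observed (uncensored) event times on the v scale and ``pi`` is the
risk-set average of the fitted covariate.  ``beta*`` solves ``g(beta*) = 0``.
At ``gamma = 0`` the integrand vanishes identically at ``b = beta``, so the
reduced model is consistent -- every code path reduces to the identity there.

All expectations over C given x are exact finite sums for two-point laws and
Gauss-Hermite / Gauss-Legendre quadratures otherwise; the time integral uses
adaptive quadrature on ``s = log v``, with explicit breakpoints wherever the
censoring survivor has kinks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import quad_vec
from scipy.optimize import brentq

from .confounder_models import (
    BinaryConfounder, ConfounderModel, NormalConfounder, SensitivityParams,
    UniformConfounder,
)
from .exceptions import NumericalError, ValidationError

__all__ = [
    "BinaryExposure", "NormalExposure",
    "NoCensoring", "UniformCensoring", "ExponentialCensoring",
    "ScenarioSpec", "BiasResult",
    "score_limit", "solve_beta_star", "binary_exposure_beta_star",
    "nocensor_beta_star", "taylor_beta_star", "rare_event_relation",
    "lin_formula_correction", "marginal_hazard_ratio", "scenario_from_dict",
]


# ---------------------------------------------------------------------------
# exposure / covariate laws

class BinaryExposure:
    """X = 1 with probability p, else 0."""

    def __init__(self, p: float):
        if not 0 < p < 1:
            raise ValidationError("exposure probability must be in (0,1)")
        self.p = float(p)
        self.binary = True

    def nodes(self):
        return np.array([0.0, 1.0]), np.array([1.0 - self.p, self.p])

    def sample(self, n, rng):
        return (rng.random(n) < self.p).astype(float)


class NormalExposure:
    """Gaussian exposure; expectations use Gauss-Legendre on a 6-sd range."""

    def __init__(self, mean: float = 0.0, sd: float = 1.0, n_quad: int = 64):
        if sd <= 0:
            raise ValidationError("sd must be positive")
        self.mean, self.sd = float(mean), float(sd)
        self.binary = False
        from scipy.special import roots_legendre
        u, w = roots_legendre(n_quad)
        lo, hi = mean - 6 * sd, mean + 6 * sd
        x = 0.5 * (lo + hi) + 0.5 * (hi - lo) * u
        pdf = np.exp(-0.5 * ((x - mean) / sd) ** 2)
        wq = w * pdf
        self._x, self._w = x, wq / wq.sum()

    def nodes(self):
        return self._x, self._w

    def sample(self, n, rng):
        return self.mean + self.sd * rng.standard_normal(n)


# ---------------------------------------------------------------------------
# censoring laws

class NoCensoring:
    kind = "none"

    def survivor(self, t, x):
        return np.ones_like(np.asarray(t, dtype=float))

    def sample(self, x, rng):
        return np.full(np.asarray(x).shape, np.inf)

    def prob_censored(self, rate, x):
        return 0.0

    def breakpoints(self, x):
        return []


class UniformCensoring:
    """Censoring time ~ Uniform(0, theta(x)); theta may depend on the arm."""

    kind = "uniform"

    def __init__(self, theta):
        self.theta = theta

    def _theta(self, x):
        if callable(self.theta):
            return float(self.theta(x))
        if isinstance(self.theta, dict):
            return float(self.theta[float(x)])
        return float(self.theta)

    def survivor(self, t, x):
        th = self._theta(x)
        return np.clip(1.0 - np.asarray(t, dtype=float) / th, 0.0, 1.0)

    def sample(self, x, rng):
        x = np.asarray(x, dtype=float)
        th = np.array([self._theta(v) for v in np.atleast_1d(x)])
        return rng.uniform(0.0, th)

    def prob_censored(self, rate, x):
        # T | rate ~ Exp(rate): P(U(0,theta) < T) = (1 - exp(-rate theta)) / (rate theta)
        z = rate * self._theta(x)
        return float(-np.expm1(-z) / z) if z > 0 else 1.0

    def breakpoints(self, x):
        return [self._theta(x)]


class ExponentialCensoring:
    """Censoring time ~ Exponential(rate(x))."""

    kind = "exponential"

    def __init__(self, rate):
        self.rate = rate

    def _rate(self, x):
        if callable(self.rate):
            return float(self.rate(x))
        if isinstance(self.rate, dict):
            return float(self.rate[float(x)])
        return float(self.rate)

    def survivor(self, t, x):
        return np.exp(-self._rate(x) * np.asarray(t, dtype=float))

    def sample(self, x, rng):
        x = np.asarray(x, dtype=float)
        r = np.array([self._rate(v) for v in np.atleast_1d(x)])
        return rng.exponential(1.0 / r)

    def prob_censored(self, rate, x):
        rho = self._rate(x)
        return float(rho / (rho + rate))

    def breakpoints(self, x):
        return []


# ---------------------------------------------------------------------------
# scenario

@dataclass
class ScenarioSpec:
    """Complete data-generating mechanism for bias analysis and simulation.

    ``beta`` is the true exposure log-hazard ratio; ``covariates`` holds
    measured covariates as (name, law, coefficient) triples; the baseline
    hazard is exponential with rate ``baseline_rate``.
    """

    exposure: object
    confounder: ConfounderModel
    gamma: float
    beta: float
    baseline_rate: float = 1.0
    censoring: object = field(default_factory=NoCensoring)
    covariates: tuple = ()

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ValidationError("baseline_rate must be positive")
        if not np.isfinite(self.gamma):
            raise ValidationError("gamma must be finite")

    @property
    def k_fit(self) -> int:
        return 1 + len(self.covariates)

    def true_coefficients(self) -> np.ndarray:
        return np.array([self.beta, *[c[2] for c in self.covariates]], dtype=float)

    def cells(self):
        """Discrete joint representation of (X, Z, C).

        Returns (weights, x values, fitted-covariate matrix U, true eta).
        Exact for two-point laws; quadrature nodes otherwise.
        """
        xs, wx = self.exposure.nodes()
        parts_v, parts_w = [xs], [wx]
        for _, law, _ in self.covariates:
            zv, zw = law.nodes()
            parts_v.append(zv)
            parts_w.append(zw)
        grids = np.meshgrid(*parts_v, indexing="ij")
        wgrids = np.meshgrid(*parts_w, indexing="ij")
        U = np.column_stack([g.ravel() for g in grids])
        w_xz = np.prod([g.ravel() for g in wgrids], axis=0)

        rows_w, rows_x, rows_u, rows_eta = [], [], [], []
        coefs = self.true_coefficients()
        for u_row, w0 in zip(U, w_xz):
            cv, cw = self.confounder.nodes(u_row[0])
            rows_w.append(w0 * cw)
            rows_x.append(np.full(cv.size, u_row[0]))
            rows_u.append(np.tile(u_row, (cv.size, 1)))
            rows_eta.append(float(u_row @ coefs) + self.gamma * cv)
        return (np.concatenate(rows_w), np.concatenate(rows_x),
                np.vstack(rows_u), np.concatenate(rows_eta))

    def t_of_v(self, v):
        return np.asarray(v, dtype=float) / self.baseline_rate


@dataclass
class BiasResult:
    """beta*, bias and diagnostics from one asymptotic-bias evaluation."""

    beta_star: np.ndarray
    bias: np.ndarray
    method: str
    diagnostics: dict = field(default_factory=dict)

    @property
    def scalar(self) -> float:
        return float(np.atleast_1d(self.beta_star)[0])


# ---------------------------------------------------------------------------
# log-scale adaptive time integration

def _integrate_logscale(f, eta, scenario, epsabs=1e-10):
    """Integrate f(v) dv over (0, inf) on s = log v, splitting at censoring kinks.

    The event-time mass of a cell with log relative risk eta sits at
    v ~ exp(-eta); the s-range covers every cell's mass to ~1e-11 tails.
    """
    s_lo = -float(np.max(eta)) - 25.0
    s_hi = -float(np.min(eta)) + 5.0
    v_breaks = []
    xs, _ = scenario.exposure.nodes()
    for x in xs:
        for t_b in scenario.censoring.breakpoints(x):
            v_b = scenario.baseline_rate * t_b
            if v_b > 0:
                v_breaks.append(v_b)
    if v_breaks and _censoring_truncates(scenario):
        # no observed time can exceed the largest censoring support bound
        s_hi = min(s_hi, math.log(max(v_breaks)))
    breaks = {math.log(v) for v in v_breaks if s_lo < math.log(v) < s_hi}
    if s_hi <= s_lo:
        raise NumericalError("empty integration range (censoring removes all mass)")
    pts = [s_lo, *sorted(breaks), s_hi]
    total, err = 0.0, 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        val, e = quad_vec(lambda s: f(np.exp(s)) * np.exp(s), a, b,
                          epsabs=epsabs, epsrel=1e-9, limit=400)
        total = total + val
        err += e
    if err > 1e-6:
        raise NumericalError(f"time quadrature error estimate {err:.2e} too large")
    return total, err


def _censoring_truncates(scenario):
    # uniform censoring has bounded support: no observed times beyond max theta
    return isinstance(scenario.censoring, UniformCensoring)


# ---------------------------------------------------------------------------
# the general score limit and its root

def score_limit(beta_star, scenario: ScenarioSpec):
    """Limiting average partial-likelihood score g(beta*) of the reduced model."""
    b = np.atleast_1d(np.asarray(beta_star, dtype=float))
    if b.size != scenario.k_fit:
        raise ValidationError(f"beta_star must have length {scenario.k_fit}")
    w, x, U, eta = scenario.cells()
    Gfun = scenario.censoring.survivor
    xlv = np.unique(x)
    e_eta = np.exp(eta)
    xi = U @ b
    e_xi = np.exp(xi)

    def integrand(v):
        surv = np.exp(-v * e_eta)
        G = np.empty_like(surv)
        t = scenario.t_of_v(v)
        for lv in xlv:
            G[x == lv] = scenario.censoring.survivor(t, lv)
        ev_w = w * e_eta * surv * G           # event-density weight per cell
        risk_w = w * e_xi * surv * G          # at-risk weight under fitted model
        denom = risk_w.sum()
        if denom <= 0:
            return np.zeros(scenario.k_fit)
        pi = (risk_w @ U) / denom
        return ev_w @ U - ev_w.sum() * pi

    val, err = _integrate_logscale(integrand, eta, scenario)
    return val


def solve_beta_star(scenario: ScenarioSpec, bracket=(-10.0, 10.0), tol=1e-10) -> BiasResult:
    """Root of the limiting score: the asymptotic value of the reduced MLE."""
    beta_true = scenario.true_coefficients()
    g0 = score_limit(beta_true, scenario)
    if np.max(np.abs(g0)) < 1e-12:
        return BiasResult(beta_star=beta_true.copy(), bias=np.zeros_like(beta_true),
                          method="score-limit", diagnostics={"residual": float(np.max(np.abs(g0)))})
    if scenario.k_fit == 1:
        f = lambda bb: float(score_limit([bb], scenario)[0])
        lo, hi = bracket
        flo, fhi = f(lo), f(hi)
        if flo * fhi > 0:
            lo, hi = 2 * lo, 2 * hi
            flo, fhi = f(lo), f(hi)
            if flo * fhi > 0:
                raise NumericalError(
                    f"no sign change of the limiting score in [{lo}, {hi}]; supply a manual bracket")
        root = brentq(f, lo, hi, xtol=tol)
        res = abs(f(root))
        bs = np.array([root])
    else:
        bs = beta_true.copy()
        res = np.max(np.abs(score_limit(bs, scenario)))
        for it in range(60):
            g = score_limit(bs, scenario)
            res = float(np.max(np.abs(g)))
            if res < 1e-9:
                break
            J = np.empty((bs.size, bs.size))
            h = 1e-6
            for j in range(bs.size):
                bp = bs.copy()
                bp[j] += h
                J[:, j] = (score_limit(bp, scenario) - g) / h
            step = np.linalg.solve(J, -g)
            lam = 1.0
            for _ in range(20):
                cand = bs + lam * step
                if np.max(np.abs(score_limit(cand, scenario))) < res:
                    bs = cand
                    break
                lam *= 0.5
            else:
                raise NumericalError("damped Newton stalled while solving the score system")
        else:
            raise NumericalError("score-system Newton did not converge")
    result = BiasResult(beta_star=bs, bias=bs - beta_true, method="score-limit",
                        diagnostics={"residual": float(res)})
    return result


# ---------------------------------------------------------------------------
# binary-exposure special paths

def _arm_profiles(scenario):
    """Per-arm confounder-integrated event-density and at-risk weights."""
    if not getattr(scenario.exposure, "binary", False):
        raise ValidationError("this operation requires a binary exposure")
    if scenario.covariates:
        raise ValidationError("binary special case supports the exposure-only model")
    out = {}
    for xv in (0.0, 1.0):
        c, wc = scenario.confounder.nodes(xv)
        eta = scenario.beta * xv + scenario.gamma * np.asarray(c)
        out[xv] = (np.asarray(wc), np.exp(eta))
    return out


def binary_exposure_beta_star(scenario: ScenarioSpec, tol=1e-12, max_iter=200) -> BiasResult:
    """beta* for binary exposure via the arm-ratio fixed point.

    For binary X the score root satisfies

        e^{beta*} = Int A1 W0 / S dv  /  Int A0 W1 / S dv,
        S(v) = p e^{beta*} W1(v) + (1-p) W0(v),

    with per-arm event-density A_x(v) = E_C[e^eta exp(-v e^eta)|x] G(t|x) and
    at-risk weight W_x(v) = E_C[exp(-v e^eta)|x] G(t|x).  The fixed point is
    iterated to convergence (Brent fallback).  Diagnostics carry the ratio of
    uncensoring rates between the control and treatment arms.
    """
    prof = _arm_profiles(scenario)
    p = scenario.exposure.p
    w0, r0 = prof[0.0]
    w1, r1 = prof[1.0]
    eta_all = np.concatenate([np.log(r0), np.log(r1)])
    Gc = scenario.censoring.survivor

    def arm_funcs(v):
        t = scenario.t_of_v(v)
        G0 = float(Gc(t, 0.0))
        G1 = float(Gc(t, 1.0))
        s0v = np.exp(-v * r0)
        s1v = np.exp(-v * r1)
        A0 = float(np.sum(w0 * r0 * s0v)) * G0
        A1 = float(np.sum(w1 * r1 * s1v)) * G1
        W0 = float(np.sum(w0 * s0v)) * G0
        W1 = float(np.sum(w1 * s1v)) * G1
        return A0, A1, W0, W1

    def ratio(b):
        eb = math.exp(b)

        def f(v):
            A0, A1, W0, W1 = arm_funcs(v)
            S = p * eb * W1 + (1 - p) * W0
            if S <= 0:
                return np.zeros(2)
            return np.array([A1 * W0 / S, A0 * W1 / S])

        (num, den), _ = _integrate_logscale(f, eta_all, scenario)
        return math.log(num / den)

    b = scenario.beta
    converged = False
    for it in range(max_iter):
        b_new = ratio(b)
        if abs(b_new - b) < tol:
            b = b_new
            converged = True
            break
        b = 0.5 * b + 0.5 * b_new  # damped fixed point
    if not converged:
        b = brentq(lambda bb: ratio(bb) - bb, -10, 10, xtol=1e-12)

    # uncensoring rates per arm: P(Delta=1 | x)
    def dens(v):
        A0, A1, _, _ = arm_funcs(v)
        return np.array([A0, A1])

    (P0, P1), _ = _integrate_logscale(dens, eta_all, scenario)
    return BiasResult(beta_star=np.array([b]), bias=np.array([b - scenario.beta]),
                      method="binary-arm-ratio",
                      diagnostics={"residual": abs(ratio(b) - b),
                                   "uncensoring_rate_ratio": P0 / P1,
                                   "uncensoring_prob": {0: P0, 1: P1}})


def nocensor_beta_star(scenario: ScenarioSpec) -> BiasResult:
    """Closed no-censoring form for binary exposure.

    Without censoring the observed time given (x, c) is exponential with rate
    ``lambda0 exp(eta)`` and the baseline rate cancels from the score on the
    cumulative-hazard scale, so beta* does not depend on lambda0 at all.
    """
    if not isinstance(scenario.censoring, NoCensoring):
        raise ValidationError("the closed no-censoring form requires censoring law = none")
    # evaluate on the v scale with unit baseline: lambda0-invariant by construction
    res = binary_exposure_beta_star(replace(scenario, baseline_rate=1.0))
    return BiasResult(beta_star=res.beta_star, bias=res.bias, method="nocensor-closed-form",
                      diagnostics=res.diagnostics)


def taylor_beta_star(scenario: ScenarioSpec, order: str = "first") -> BiasResult:
    """First-order Taylor approximation: one Newton step of the score from beta.

    Exact at gamma = 0; the error grows with |gamma| since the neglected terms
    are second order in the bias.
    """
    if order != "first":
        raise ValidationError("only the first-order expansion is provided")
    beta_true = scenario.true_coefficients()
    g = score_limit(beta_true, scenario)
    K = beta_true.size
    J = np.empty((K, K))
    h = 1e-6
    for j in range(K):
        bp = beta_true.copy()
        bp[j] += h
        J[:, j] = (score_limit(bp, scenario) - g) / h
    bias = np.linalg.solve(J, -g)
    return BiasResult(beta_star=beta_true + bias, bias=bias, method="taylor",
                      diagnostics={"score_at_truth": g.tolist()})


def rare_event_relation(beta, scenario: ScenarioSpec) -> BiasResult:
    """beta* under the rare-event (heavy-censoring) simplification.

    When events are rare the risk-set composition is unaffected by failures
    and, for exposure-independent censoring, the score relation collapses to

        E[X e^{b X}] / E[e^{b X}] = E[X e^{beta X} m(gamma|X)] / E[e^{beta X} m(gamma|X)]

    with m the confounder mgf given x.  For binary X this is the classic
    correction b = beta + log(m(gamma|1)/m(gamma|0)); for a balanced omitted
    covariate it reduces to no adjustment at all.
    """
    beta = float(np.atleast_1d(beta)[0])
    m = scenario.confounder.mgf
    g = scenario.gamma
    if getattr(scenario.exposure, "binary", False):
        b = beta + math.log(m(g, 1.0) / m(g, 0.0))
    else:
        xs, wx = scenario.exposure.nodes()
        mx = np.array([m(g, xv) for xv in xs])
        target = float(np.sum(wx * xs * np.exp(beta * xs) * mx) /
                       np.sum(wx * np.exp(beta * xs) * mx))

        def f(bb):
            e = np.exp(bb * xs)
            return float(np.sum(wx * xs * e) / np.sum(wx * e)) - target

        b = brentq(f, -20, 20, xtol=1e-12)
    return BiasResult(beta_star=np.array([b]), bias=np.array([b - beta]),
                      method="rare-event", diagnostics={"residual": 0.0})


def lin_formula_correction(beta_star: float, params: SensitivityParams) -> float:
    """Invert the rare-event relation: corrected estimate given beta*.

    Exact inverse of :func:`rare_event_relation` for binary exposure:
    beta = beta* - log(m(gamma|1)/m(gamma|0)).
    """
    m = params.confounder.mgf
    return float(beta_star) - math.log(m(params.gamma, 1.0) / m(params.gamma, 0.0))


def marginal_hazard_ratio(scenario: ScenarioSpec, t: float) -> float:
    """Ratio of marginal hazards (C integrated out) between the two arms at t.

    The marginal hazard in arm x is
    lambda0(t) e^{beta x} E[e^{gamma C} S(t|x,C)|x] / E[S(t|x,C)|x]; with
    gamma != 0 and survivors diverging between C strata the ratio varies with
    t -- the fitted reduced coefficient averages these log ratios over time.
    At t -> 0 it equals exp(beta) m(gamma|1)/m(gamma|0); as gamma -> +/-inf
    it tends to finite limits because the high-risk stratum is exhausted.
    """
    if not getattr(scenario.exposure, "binary", False):
        raise ValidationError("marginal hazard ratio requires binary exposure")
    v = scenario.baseline_rate * float(t)
    out = {}
    for xv in (0.0, 1.0):
        c, wc = scenario.confounder.nodes(xv)
        rr = np.exp(scenario.beta * xv + scenario.gamma * np.asarray(c))
        surv = np.exp(-v * rr)
        out[xv] = float(np.sum(wc * rr * surv) / np.sum(wc * surv))
    return out[1.0] / out[0.0]


# ---------------------------------------------------------------------------
# config plumbing

def scenario_from_dict(cfg: dict) -> ScenarioSpec:
    """Build a ScenarioSpec from a plain mapping (parsed YAML/JSON config)."""
    exp = cfg.get("exposure", {"kind": "binary", "p": 0.5})
    if exp.get("kind", "binary") == "binary":
        exposure = BinaryExposure(exp.get("p", 0.5))
    elif exp["kind"] == "normal":
        exposure = NormalExposure(exp.get("mean", 0.0), exp.get("sd", 1.0))
    else:
        raise ValidationError(f"unknown exposure kind {exp.get('kind')}")

    conf = cfg.get("confounder", {"kind": "binary", "p1": 0.5, "p0": 0.5})
    kind = conf.get("kind", "binary")
    if kind == "binary":
        confounder = BinaryConfounder(conf["p1"], conf["p0"])
    elif kind == "normal":
        confounder = NormalConfounder(conf.get("mean0", 0.0), conf.get("slope", 0.0),
                                      conf.get("sd", 1.0))
    elif kind == "uniform":
        confounder = UniformConfounder(conf.get("a", 0.0), conf.get("b", 1.0))
    else:
        raise ValidationError(f"unknown confounder kind {kind}")

    cens_cfg = cfg.get("censoring", {"kind": "none"})
    ckind = cens_cfg.get("kind", "none")
    if ckind == "none":
        censoring = NoCensoring()
    elif ckind == "uniform":
        theta = cens_cfg["theta"]
        if isinstance(theta, dict):
            theta = {float(k): float(v) for k, v in theta.items()}
        censoring = UniformCensoring(theta)
    elif ckind == "exponential":
        rate = cens_cfg["rate"]
        if isinstance(rate, dict):
            rate = {float(k): float(v) for k, v in rate.items()}
        censoring = ExponentialCensoring(rate)
    else:
        raise ValidationError(f"unknown censoring kind {ckind}")

    return ScenarioSpec(exposure=exposure, confounder=confounder,
                        gamma=float(cfg.get("gamma", 0.0)), beta=float(cfg.get("beta", 0.0)),
                        baseline_rate=float(cfg.get("baseline_rate", 1.0)), censoring=censoring)
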