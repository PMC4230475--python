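"""Conditional laws of the omitted covariate C given exposure x.

A :class:`ConfounderModel` is a sensitivity input, never estimated from data.
It must supply three things:

* ``nodes(x)``       -- a discrete representation ``(values, weights)`` of the
  law of C given ``x`` (exact for two-point laws, quadrature otherwise),
* ``mgf(s, x)``      -- the conditional moment generating function
  ``E[exp(s C) | x]``,
* ``sample(x, rng)`` -- reproducible draws of C given a vector of exposures.

Every expectation the bias and correction formulae need reduces to weighted
sums over ``nodes(x)``; for the binary kind these sums are exact two-point
expectations and no Monte Carlo path is ever invoked.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import roots_hermitenorm, roots_legendre
from scipy.stats import norm

from .exceptions import NumericalError, ValidationError

__all__ = [
    "ConfounderModel", "BinaryConfounder", "NormalConfounder",
    "UniformConfounder", "CustomConfounder", "SensitivityParams",
    "mgf", "sample_c", "posterior_expectation_exp_gamma_c",
]


class ConfounderModel:
    """Abstract conditional law of C given exposure x."""

    kind = "custom"

    def nodes(self, x: float) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def mgf(self, s: float, x: float) -> float:
        """E[exp(s C) | x]; default evaluates the node representation."""
        c, w = self.nodes(x)
        out = float(np.sum(w * np.exp(s * c)))
        if not np.isfinite(out):
            raise NumericalError(f"mgf({s}, x={x}) is not finite")
        return out

    def sample(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def expectation(self, weight, gamma: float, x: float) -> float:
        """E[weight(C) * exp(gamma C) | x] by the node representation."""
        c, w = self.nodes(x)
        out = float(np.sum(w * np.asarray(weight(c)) * np.exp(gamma * c)))
        if not np.isfinite(out):
            raise NumericalError("confounder expectation is not finite")
        return out


class BinaryConfounder(ConfounderModel):
    """Bernoulli omitted covariate with prevalence depending on exposure.

    For binary exposure, ``p1 = P(C=1 | X=1)`` and ``p0 = P(C=1 | X=0)``.
    ``p1 - p0`` measures the strength of confounding; ``p1 == p0`` is the
    balanced-covariate case.  For continuous exposure a logistic dependence
    ``P(C=1|x) = expit(a + b x)`` can be calibrated to a target marginal
    prevalence and correlation with X via :meth:`from_correlation`.
    """

    kind = "binary"

    def __init__(self, p1: float, p0: float):
        for name, p in (("p1", p1), ("p0", p0)):
            if not 0.0 < p < 1.0:
                raise ValidationError(f"{name} must lie strictly in (0,1); got {p}")
        self.p1 = float(p1)
        self.p0 = float(p0)
        self._logistic = None  # (a, b) when calibrated for continuous exposure

    def prevalence(self, x: float) -> float:
        if self._logistic is not None:
            a, b = self._logistic
            return float(1.0 / (1.0 + np.exp(-(a + b * x))))
        return self.p1 if x == 1 else self.p0

    def nodes(self, x: float):
        p = self.prevalence(x)
        return np.array([0.0, 1.0]), np.array([1.0 - p, p])

    def mgf(self, s: float, x: float) -> float:
        p = self.prevalence(x)
        return float(1.0 - p + p * np.exp(s))

    def sample(self, x, rng):
        x = np.asarray(x, dtype=float)
        if self._logistic is not None:
            a, b = self._logistic
            p = 1.0 / (1.0 + np.exp(-(a + b * x)))
        else:
            p = np.where(x == 1, self.p1, self.p0)
        return (rng.random(x.shape) < p).astype(float)

    @classmethod
    def from_correlation(cls, marginal_prevalence: float, rho: float, x_mean: float, x_sd: float,
                         n_quad: int = 128) -> "BinaryConfounder":
        """Calibrate a logistic law P(C=1|x)=expit(a+bx) for Gaussian exposure.

        The two logistic parameters are root-found so that the marginal
        prevalence of C equals ``marginal_prevalence`` and corr(X, C) equals
        ``rho``.  This is the construction needed for continuous exposures
        (e.g. a deprivation score) with a binary omitted covariate.
        """
        if not 0 < marginal_prevalence < 1:
            raise ValidationError("marginal prevalence must be in (0,1)")
        if not -1 < rho < 1:
            raise ValidationError("rho must be in (-1,1)")
        z, wz = roots_hermitenorm(n_quad)
        wz = wz / np.sqrt(2 * np.pi)
        xs = x_mean + x_sd * z
        pc = marginal_prevalence

        from scipy.special import expit

        def moments(a, b):
            p = expit(a + b * xs)
            m = np.sum(wz * p)                      # P(C=1)
            exc = np.sum(wz * xs * p)               # E[X C]
            return m, exc

        def corr_given_b(b):
            # solve intercept a for the marginal prevalence at this slope
            a = brentq(lambda aa: moments(aa, b)[0] - pc, -50, 50, xtol=1e-12)
            m, exc = moments(a, b)
            cov = exc - x_mean * m
            return a, cov / (x_sd * np.sqrt(m * (1 - m)))

        lo, hi = (0.0, 50.0) if rho >= 0 else (-50.0, 0.0)
        b = brentq(lambda bb: corr_given_b(bb)[1] - rho, lo, hi, xtol=1e-10)
        a = corr_given_b(b)[0]
        model = cls(p1=0.5, p0=0.5)
        model._logistic = (a, b)
        return model


class NormalConfounder(ConfounderModel):
    """Gaussian omitted covariate: C | x ~ Normal(mean0 + slope * x, sd^2)."""

    kind = "normal"

    def __init__(self, mean0: float = 0.0, slope: float = 0.0, sd: float = 1.0, n_quad: int = 41):
        if sd <= 0:
            raise ValidationError("sd must be positive")
        self.mean0 = float(mean0)
        self.slope = float(slope)
        self.sd = float(sd)
        self._z, w = roots_hermitenorm(n_quad)
        self._w = w / np.sqrt(2 * np.pi)

    def mean(self, x: float) -> float:
        return self.mean0 + self.slope * x

    def nodes(self, x: float):
        return self.mean(x) + self.sd * self._z, self._w

    def mgf(self, s: float, x: float) -> float:
        # lognormal moment: E exp(sC) = exp(s mu + s^2 sd^2 / 2)
        return float(np.exp(s * self.mean(x) + 0.5 * s * s * self.sd * self.sd))

    def sample(self, x, rng):
        x = np.asarray(x, dtype=float)
        return self.mean0 + self.slope * x + self.sd * rng.standard_normal(x.shape)


class UniformConfounder(ConfounderModel):
    """Uniform(a, b) omitted covariate, independent of exposure.

    This is the heavy-censoring benchmark law; its mgf has the closed form
    (exp(sb) - exp(sa)) / (s (b - a)).
    """

    kind = "uniform"

    def __init__(self, a: float = 0.0, b: float = 1.0, n_quad: int = 64):
        if b <= a:
            raise ValidationError("need b > a")
        self.a, self.b = float(a), float(b)
        u, w = roots_legendre(n_quad)
        self._c = 0.5 * (self.a + self.b) + 0.5 * (self.b - self.a) * u
        self._w = 0.5 * w  # weights sum to 1

    def nodes(self, x: float):
        return self._c, self._w

    def mgf(self, s: float, x: float) -> float:
        if s == 0:
            return 1.0
        return float((np.exp(s * self.b) - np.exp(s * self.a)) / (s * (self.b - self.a)))

    def sample(self, x, rng):
        x = np.asarray(x, dtype=float)
        return rng.uniform(self.a, self.b, x.shape)


class CustomConfounder(ConfounderModel):
    """User-supplied law: a seeded sampler of C given x, optional closed-form mgf.

    Without a closed form, expectations use a fixed Monte Carlo node set
    (default 10,000 draws) drawn once from a dedicated seed, independent of
    any data-generation stream.  A relative Monte Carlo standard error above
    0.5% raises a precision warning flag on the model.
    """

    kind = "custom"

    def __init__(self, sampler, mgf_fn=None, n_mc: int = 10_000, mc_seed: int = 987_654_321):
        self._sampler = sampler
        self._mgf_fn = mgf_fn
        self.n_mc = int(n_mc)
        self._mc_seed = int(mc_seed)
        self._node_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
        self.precision_warning = False

    def nodes(self, x: float):
        if x not in self._node_cache:
            rng = np.random.default_rng(self._mc_seed)
            draws = np.asarray(self._sampler(np.full(self.n_mc, x), rng), dtype=float)
            self._node_cache[x] = (draws, np.full(self.n_mc, 1.0 / self.n_mc))
        return self._node_cache[x]

    def mgf(self, s: float, x: float) -> float:
        if self._mgf_fn is not None:
            return float(self._mgf_fn(s, x))
        return super().mgf(s, x)

    def expectation(self, weight, gamma, x):
        c, w = self.nodes(x)
        vals = np.asarray(weight(c)) * np.exp(gamma * c)
        est = float(np.sum(w * vals))
        se = float(np.std(vals) / np.sqrt(vals.size))
        if est != 0 and se / abs(est) > 0.005:
            self.precision_warning = True
        return est

    def sample(self, x, rng):
        return np.asarray(self._sampler(np.asarray(x, dtype=float), rng), dtype=float)


@dataclass
class SensitivityParams:
    """Assumed properties of the omitted covariate: its log-hazard effect
    ``gamma`` and its conditional law given exposure."""

    gamma: float
    confounder: ConfounderModel

    def __post_init__(self):
        if not np.isfinite(self.gamma):
            raise ValidationError("gamma must be finite")


# ---------------------------------------------------------------------------
# functional conveniences mirroring the model methods

def mgf(model: ConfounderModel, s: float, x: float) -> float:
    """E[exp(s C) | x]."""
    return model.mgf(s, x)


def sample_c(model: ConfounderModel, x, seed: int) -> np.ndarray:
    """Reproducible elementwise draws of C given the exposure vector."""
    return model.sample(np.asarray(x, dtype=float), np.random.default_rng(seed))


def posterior_expectation_exp_gamma_c(model: ConfounderModel, gamma: float, x: float, weight=None) -> float:
    """E[weight(C) exp(gamma C) | x]; weight defaults to 1 (the mgf)."""
    if weight is None:
        weight = lambda c: np.ones_like(np.asarray(c, dtype=float))
    return model.expectation(weight, gamma, x)


def normal_cdf(z):
    return norm.cdf(z)
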