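"""Sensitivity correction of Cox treatment-effect estimates on observed data.

Given observed data, a reduced-model fit and assumed properties of the
omitted covariate (its log-hazard effect ``gamma`` and its conditional law
given exposure), the empirical analogue of the limiting partial-likelihood
score relates each candidate true coefficient ``beta`` to the reduced-model
value ``h(beta)`` it would produce.  Inverting ``h`` at the observed
estimate yields the corrected point estimate; P-values and confidence
intervals follow by mapping the null and the Wald bounds through ``h`` and
its inverse, or by a parametric bootstrap with highest-density intervals
when the mapped sampling distribution is skewed.

The empirical score anchors three estimated ingredients to the data:

* the reduced-model Breslow increments ``dLam*_i`` at the distinct
  uncensored times are held fixed, and the true-model baseline increments
  are solved from them sequentially -- the conditional law of C among
  survivors tilts towards small ``exp(gamma c)`` as time passes, and the
  recursion tracks that tilt exactly through the confounder expectations;
* the censoring survivor enters through its reverse-role Breslow estimate
  (per exposure arm for binary exposure), giving the model-implied at-risk
  mass ``N_x G_hat(t-|x) E_C[exp(-Lam0(t) e^{beta x + gamma c}) | x]``;
* expectations over C are exact two-point sums for a binary confounder and
  quadratures for continuous kinds.

Writing ``S_ev`` for the event-intensity-weighted covariate sums under the
assumed mechanism and ``S_fit`` for the at-risk sums under a working
coefficient ``b``, the bivariate empirical score is

    F(beta, b) = sum_i dLam0_i(beta, b) [ S1_ev,i - (S1_fit,i / S0_fit,i) S0_ev,i ],
    dLam0_i = dLam*_i  S0_fit,i / S0_ev,i,

and ``h(beta)`` is the root of ``F(beta, .)``.  The same relation gives the
inverse map directly: ``h^{-1}(b)`` is the root of ``F(., b)``, so corrected
estimates need no nested solving.  At ``gamma = 0`` the mechanism is the
fitted one, ``F(beta, beta) = 0`` identically, and ``h`` is the exact
identity.  Measured covariates are profiled at their reduced-fit
coefficients, so the map acts on the exposure coordinate alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator
from scipy.stats import norm

from .confounder_models import BinaryConfounder, SensitivityParams
from .exceptions import NumericalError, ValidationError
from .io_core import SurvivalSample
from .survival_core import CoxFit, censoring_survivor

__all__ = [
    "ScoreMap", "SensitivityResult", "build_score_map", "corrected_estimate",
    "corrected_pvalue", "ci_bootstrap_hdi", "ci_bound_transform", "sensitivity_grid",
]


@dataclass
class SensitivityResult:
    """Corrected inference for one assumed (gamma, confounder-law) setting."""

    beta_corrected: float
    se_reduced: float
    ci: tuple | None
    ci_mass: float
    p_value: float | None
    method_ci: str | None
    params: SensitivityParams
    diagnostics: dict = field(default_factory=dict)


def _vector_root(f, z0, tol=1e-9, max_secant=40):
    """Elementwise root of a vectorised function: secant with bisection fallback."""
    z0 = np.atleast_1d(np.asarray(z0, dtype=float))
    z1 = z0 + 0.25
    f0, f1 = f(z0), f(z1)
    for _ in range(max_secant):
        if np.all(np.abs(f1) < tol):
            break
        denom = f1 - f0
        safe = np.abs(denom) > 1e-300
        step = np.where(safe, f1 * (z1 - z0) / np.where(safe, denom, 1.0), 0.3)
        z2 = z1 - np.clip(step, -2.0, 2.0)
        z0, f0 = z1, f1
        z1 = z2
        f1 = f(z1)
    bad = ~((np.abs(f1) < 1e-7) & np.isfinite(z1))
    if np.any(bad):
        z1 = z1.copy()

        def f_sub(zsub):
            zf = z1.copy()
            zf[bad] = zsub
            return f(zf)[bad]

        z1[bad] = _bisect_root(f_sub, z1[bad])
    return z1


def _bisect_root(f_sub, centre):
    """Bracket-expanding bisection for stubborn components (rarely needed)."""
    centre = np.where(np.isfinite(centre), centre, 0.0)
    lo = centre - 0.5
    hi = centre + 0.5
    flo, fhi = f_sub(lo), f_sub(hi)
    for _ in range(40):
        need = flo * fhi > 0
        if not np.any(need):
            break
        width = hi - lo
        lo = np.where(need, lo - 0.7 * width, lo)
        hi = np.where(need, hi + 0.7 * width, hi)
        flo, fhi = f_sub(lo), f_sub(hi)
    else:
        raise NumericalError("no sign change found for the empirical score root")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        fm = f_sub(mid)
        left = flo * fm <= 0
        hi = np.where(left, mid, hi)
        lo = np.where(left, lo, mid)
        flo = np.where(left, flo, fm)
    return 0.5 * (lo + hi)


class _AnchoredScore:
    """The bivariate empirical score F(beta, b), vectorised over pairs.

    One instance precomputes everything that depends only on the data and the
    assumed sensitivity parameters; ``score`` then runs the sequential
    baseline recursion for a whole batch of (beta, b) pairs at once.
    """

    def __init__(self, sample: SurvivalSample, fit: CoxFit, params: SensitivityParams,
                 censoring_mode: str = "auto"):
        iexp = fit.names.index("exposure")
        self.beta_hat_star = float(fit.coefficients[iexp])
        self.se = float(np.sqrt(fit.covariance[iexp, iexp]))
        gamma = params.gamma

        # collapse subjects onto unique (exposure, profiled covariate offset)
        other = [n for n in fit.names if n != "exposure"]
        offsets = np.zeros(sample.n)
        if other:
            Z = sample.covariates[other].to_numpy(float)
            bz = np.array([fit.coefficients[fit.names.index(n)] for n in other])
            offsets = Z @ bz
        key = np.column_stack([sample.exposure, offsets])
        _, inv, counts = np.unique(np.round(key, 12), axis=0,
                                   return_inverse=True, return_counts=True)
        G = counts.size
        x_g = np.empty(G)
        o_g = np.empty(G)
        for g in range(G):
            j = np.flatnonzero(inv == g)[0]
            x_g[g], o_g[g] = sample.exposure[j], offsets[j]
        self.x_g, self.o_g, self.N_g = x_g, o_g, counts.astype(float)

        # distinct uncensored times, multiplicities, per-group at-risk counts
        y_u, d_u = np.unique(np.sort(sample.time[sample.event == 1]), return_counts=True)
        self.m = y_u.size
        R = np.empty((self.m, G))
        for g in range(G):
            tg = np.sort(sample.time[inv == g])
            R[:, g] = tg.size - np.searchsorted(tg, y_u, side="left")

        # reduced-model Breslow increments, anchored to the data
        self.dLstar = d_u / (R * np.exp(self.beta_hat_star * x_g + o_g)[None, :]).sum(axis=1)
        self._norm = 1.0 / d_u.sum()  # report the score per observed event

        # reverse-role Breslow censoring survivor at y_i- per group
        cs = censoring_survivor(sample, mode=censoring_mode)
        Gmat = np.empty((self.m, G))
        for g in range(G):
            curve = cs[float(x_g[g])] if isinstance(cs, dict) else cs
            Gmat[:, g] = curve.left_limit(y_u)
        self.AG = self.N_g[None, :] * Gmat                      # (m, G)

        # confounder nodes flattened over (group, node) pairs
        node_w, node_rrb, node_group = [], [], []
        for g in range(G):
            cv, cw = params.confounder.nodes(x_g[g])
            node_w.extend(np.asarray(cw, dtype=float))
            node_rrb.extend(np.exp(gamma * np.asarray(cv, dtype=float)))
            node_group.extend([g] * len(cw))
        self.Wf = np.asarray(node_w)
        self.RRb = np.asarray(node_rrb)
        self.xg_f = x_g[np.asarray(node_group)]
        self.og_f = o_g[np.asarray(node_group)]
        self.agg = np.zeros((len(node_w), G))
        self.agg[np.arange(len(node_w)), node_group] = 1.0

    def score(self, betas, bs):
        """F(beta_j, b_j) for paired vectors; the recursion is batched."""
        betas = np.atleast_1d(np.asarray(betas, dtype=float))
        bs = np.atleast_1d(np.asarray(bs, dtype=float))
        nP = betas.size
        x_g, o_g, AG = self.x_g, self.o_g, self.AG
        with np.errstate(over="ignore", under="ignore"):
            rr = np.exp(np.clip(betas[:, None] * self.xg_f[None, :] + self.og_f[None, :],
                                -700, 700)) * self.RRb[None, :]     # (nP, K)
            ebx = np.exp(np.clip(bs[:, None] * x_g[None, :] + o_g[None, :], -700, 700))
            Wrr = self.Wf[None, :] * rr
            Wf = self.Wf[None, :]
            lam = np.zeros(nP)
            total = np.zeros(nP)
            for i in range(self.m):
                E = np.exp(-lam[:, None] * rr)
                mu1 = (Wrr * E) @ self.agg                          # (nP, G)
                mu0 = (Wf * E) @ self.agg
                ev = AG[i][None, :] * mu1
                s0ev = np.maximum(ev.sum(axis=1), 1e-290)
                s1ev = ev @ x_g
                fitw = AG[i][None, :] * mu0 * ebx
                s0f = np.maximum(fitw.sum(axis=1), 1e-290)
                s1f = fitw @ x_g
                dlam0 = self.dLstar[i] * s0f / s0ev
                total += dlam0 * (s1ev - (s1f / s0f) * s0ev)
                lam = np.minimum(lam + dlam0, 1e7)
        return total * self._norm

    def solve_b(self, betas, init_shift=0.0):
        """h(beta): root of F(beta, .) for each beta."""
        betas = np.atleast_1d(np.asarray(betas, dtype=float))
        return _vector_root(lambda z: self.score(betas, z), betas + init_shift)

    def solve_beta(self, bs, init_shift=0.0):
        """h^{-1}(b): root of F(., b) for each target b."""
        bs = np.atleast_1d(np.asarray(bs, dtype=float))
        return _vector_root(lambda z: self.score(z, bs), bs + init_shift)


class ScoreMap:
    """The map h: beta -> beta* defined by the empirical score equations.

    ``h`` and ``h_inverse`` are roots of the same bivariate score in the two
    arguments; a grid of ``h`` over the working range (default 50 points)
    doubles as the monotonicity check and as the interpolation table for
    vectorised (bootstrap) inversion.
    """

    def __init__(self, engine: _AnchoredScore | None, beta_hat_star, se, params,
                 grid_halfwidth=5.0, grid_points=50):
        self._eng = engine
        self.beta_hat_star = float(beta_hat_star)
        self.se = float(se)
        self.params = params
        self.is_identity = (params.gamma == 0.0)
        self.monotone = True
        self.range_saturated = False
        self.grid_beta = None
        self.grid_bstar = None
        # pilot shift: the rare-event correction approximates h(beta) - beta
        try:
            from .bias_engine import lin_formula_correction
            self._shift = self.beta_hat_star - lin_formula_correction(self.beta_hat_star, params)
        except Exception:
            self._shift = 0.0
        if not self.is_identity:
            self._build_grid(grid_halfwidth, grid_points)

    # -- forward map -------------------------------------------------------
    def h(self, beta: float) -> float:
        if self.is_identity:
            return float(beta)
        return float(self._eng.solve_b([beta], self._shift)[0])

    def _build_grid(self, halfwidth, points):
        lo_t = self.beta_hat_star - halfwidth * self.se
        hi_t = self.beta_hat_star + halfwidth * self.se
        centre = self.beta_hat_star - self._shift
        span = halfwidth * self.se + 0.2
        prev_width = -np.inf
        for _ in range(10):
            beta_grid = np.linspace(centre - span, centre + span, points)
            bstar = self._eng.solve_b(beta_grid, self._shift)
            if bstar.min() <= lo_t and bstar.max() >= hi_t:
                break
            width = bstar.max() - bstar.min()
            if width - prev_width < 1e-3 * max(self.se, 1e-6):
                # h has a bounded range narrower than the Wald band; keep the
                # saturated grid and let out-of-range inversions fail loudly
                self.range_saturated = True
                break
            prev_width = width
            span *= 1.8
        else:
            raise NumericalError("score map could not cover the Wald range of beta*")
        self.grid_beta, self.grid_bstar = beta_grid, bstar
        self.monotone = bool(np.all(np.diff(bstar) > 0))

    # -- inverse map -------------------------------------------------------
    def h_inverse(self, bstar: float, tol: float = 1e-9) -> float:
        if self.is_identity:
            return float(bstar)
        g_s = self.grid_bstar
        if not self.monotone:
            i = int(np.argmin(np.abs(g_s - bstar)))
            return float(self.grid_beta[i])
        if bstar < g_s[0] or bstar > g_s[-1]:
            raise ValidationError(
                f"beta*={bstar:.4g} outside the invertible range [{g_s[0]:.4g}, {g_s[-1]:.4g}]")
        beta = float(self._eng.solve_beta([bstar], -self._shift)[0])
        if abs(float(self._eng.score([beta], [bstar])[0])) > 1e-7:
            raise NumericalError("inverse score map failed its residual check")
        return beta

    def h_inverse_many(self, bstars: np.ndarray) -> np.ndarray:
        """Vectorised inversion through the monotone grid (PCHIP)."""
        bstars = np.asarray(bstars, dtype=float)
        if self.is_identity:
            return bstars.copy()
        if not self.monotone:
            idx = np.argmin(np.abs(self.grid_bstar[None, :] - bstars[:, None]), axis=1)
            return self.grid_beta[idx]
        interp = PchipInterpolator(self.grid_bstar, self.grid_beta, extrapolate=False)
        return np.asarray(interp(bstars))


def build_score_map(sample: SurvivalSample, fit: CoxFit, params: SensitivityParams,
                    censoring_mode: str = "auto", grid_points: int = 50) -> ScoreMap:
    """Assemble the empirical score map h relating true and reduced coefficients.

    At ``gamma = 0`` the mechanism is the fitted one and ``h`` is the exact
    identity.  Otherwise the map is defined by the anchored empirical score
    described in the module docstring: reduced-model Breslow increments,
    reverse-role censoring survivors per arm, and closed-form confounder
    expectations; monotonicity is verified on a grid over the Wald range of
    the reduced estimate.
    """
    if fit.n != sample.n or fit.n_events != sample.n_events:
        raise ValidationError("fit does not match sample")
    iexp = fit.names.index("exposure")
    beta_hat_star = float(fit.coefficients[iexp])
    se = float(np.sqrt(fit.covariance[iexp, iexp]))
    if params.gamma == 0.0:
        return ScoreMap(None, beta_hat_star, se, params)
    engine = _AnchoredScore(sample, fit, params, censoring_mode)
    return ScoreMap(engine, beta_hat_star, se, params, grid_points=grid_points)


def corrected_estimate(score_map: ScoreMap, fit: CoxFit) -> SensitivityResult:
    """Point estimate of the true exposure coefficient: h^{-1}(beta_hat*)."""
    beta_c = score_map.h_inverse(score_map.beta_hat_star)
    return SensitivityResult(beta_corrected=beta_c, se_reduced=score_map.se,
                             ci=None, ci_mass=0.95, p_value=None, method_ci=None,
                             params=score_map.params,
                             diagnostics={"monotone": score_map.monotone})


def corrected_pvalue(score_map: ScoreMap, fit: CoxFit, null_beta: float = 0.0) -> float:
    """Two-sided P-value for H0: beta = null_beta under the assumed mechanism.

    The null on the true coefficient is equivalent to beta* = h(null_beta),
    tested against the reduced estimate and its standard error by the normal
    approximation.
    """
    z = (score_map.beta_hat_star - score_map.h(null_beta)) / score_map.se
    return float(2.0 * norm.sf(abs(z)))


def ci_bound_transform(score_map: ScoreMap, fit: CoxFit, mass: float = 0.95):
    """CI by mapping the Wald bounds of beta* through the inverse score map."""
    if not score_map.monotone:
        raise ValidationError("score map is not monotone; use the bootstrap-HDI interval")
    z = norm.ppf(0.5 * (1.0 + mass))
    lo = score_map.h_inverse(score_map.beta_hat_star - z * score_map.se)
    hi = score_map.h_inverse(score_map.beta_hat_star + z * score_map.se)
    return (lo, hi) if lo <= hi else (hi, lo)


def ci_bootstrap_hdi(score_map: ScoreMap, fit: CoxFit, B: int = 2000, mass: float = 0.95,
                     seed: int = 0):
    """Parametric-bootstrap highest-density interval for the corrected estimate.

    B draws from Normal(beta_hat*, se^2) are mapped through h^{-1}; the HDI is
    the shortest interval containing ceil(mass * B) of the mapped points.
    """
    if B < 500:
        raise ValidationError("B must be at least 500")
    rng = np.random.default_rng(seed)
    draws = rng.normal(score_map.beta_hat_star, score_map.se, int(B))
    mapped = score_map.h_inverse_many(draws)
    bad = ~np.isfinite(mapped)
    if bad.mean() > 0.01:
        raise NumericalError(f"inverse map failed on {bad.mean():.1%} of bootstrap draws")
    mapped = np.sort(mapped[~bad])
    k = math.ceil(mass * mapped.size)
    widths = mapped[k - 1:] - mapped[:mapped.size - k + 1]
    i = int(np.argmin(widths))
    return (float(mapped[i]), float(mapped[i + k - 1]))


def sensitivity_grid(sample: SurvivalSample, fit: CoxFit, gamma_grid, confounder_grid,
                     outputs=("point",), null_beta: float = 0.0, ci_mass: float = 0.95,
                     ci_method: str = "bound") -> pd.DataFrame:
    """Corrected results over a grid of assumed (gamma, confounder-law) cells.

    ``confounder_grid`` holds ConfounderModel instances or (p1, p0) pairs.
    Solver failures in a cell are recorded in its ``status`` column instead of
    aborting the grid, so the table is always complete and contour-ready.
    """
    gamma_grid = list(gamma_grid)
    confounder_grid = list(confounder_grid)
    if not gamma_grid or not confounder_grid:
        raise ValidationError("gamma and confounder grids must be non-empty")
    rows = []
    for conf in confounder_grid:
        model = BinaryConfounder(*conf) if isinstance(conf, (tuple, list)) else conf
        label = (f"p1={model.p1:g},p0={model.p0:g}" if isinstance(model, BinaryConfounder)
                 else type(model).__name__)
        for gamma in gamma_grid:
            row = {"gamma": float(gamma), "confounder": label}
            if isinstance(model, BinaryConfounder):
                row["p1"], row["p0"] = model.p1, model.p0
                row["dp"] = model.p1 - model.p0
            try:
                params = SensitivityParams(gamma=float(gamma), confounder=model)
                smap = build_score_map(sample, fit, params)
                if "point" in outputs:
                    row["point"] = smap.h_inverse(smap.beta_hat_star)
                if "p-value" in outputs:
                    row["p_value"] = corrected_pvalue(smap, fit, null_beta)
                if "ci-lower" in outputs or "ci-upper" in outputs:
                    if ci_method == "bound":
                        lo, hi = ci_bound_transform(smap, fit, ci_mass)
                    else:
                        lo, hi = ci_bootstrap_hdi(smap, fit, mass=ci_mass)
                    if "ci-lower" in outputs:
                        row["ci_lower"] = lo
                    if "ci-upper" in outputs:
                        row["ci_upper"] = hi
                row["status"] = "ok"
            except Exception as exc:  # cell-level failure: record, continue
                row["status"] = f"failed: {type(exc).__name__}"
            rows.append(row)
    return pd.DataFrame(rows)
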