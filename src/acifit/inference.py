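"""Maximum-likelihood curve fitting with likelihood-ratio confidence intervals.

Measurement noise on An is modelled as iid Gaussian, so the negative
log-likelihood is NLL = N·ln(σ√(2π)) + SSR/(2σ²) and the location of
its minimum over the model parameters does not depend on σ.  Fitting
proceeds in three stages:

1.  a derivative-free global search (differential evolution, seeded)
    over box bounds at σ = 1, followed by an optional simplex polish;
2.  σ is set to the RMSE of the best fit, giving true likelihoods;
3.  each fitted parameter is varied one at a time (the others held at
    their best-fit values) to find the contiguous region where the
    relative likelihood L/Lmax stays at or above a threshold (default
    0.147, which reproduces ~95% Gaussian intervals).

A parameter whose relative likelihood never falls below the threshold
out to a wide search bound has an unbounded confidence interval: its
model process is not evident in the curve, the best-fit value is
arbitrary, and the estimate is reported as NA (the policy can be
disabled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import differential_evolution, minimize

from . import c3_model, c4_model, variable_j
from .errors import AcifitError, ConfigurationError, DomainError
from .gasex_io import ResponseCurveTable
from .temperature import evaluate_preset

#: NLL assigned to parameter vectors where the model cannot be evaluated
PENALTY_NLL = 1e10

#: floor applied to the σ estimate so noise-free fits stay numerically sane
SIGMA_FLOOR = 1e-6

LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass
class OptimizerSettings:
    """Differential-evolution and polish settings (deterministic given seed)."""

    popsize: int = 10          # population = popsize × n_fit_params
    maxiter: int = 500
    tol: float = 1e-8
    mutation: tuple = (0.5, 1.0)
    recombination: float = 0.7
    polish: bool = True
    seed: int = 0


@dataclass
class FitConfig:
    fit_params: list[str] | None = None      # None → model defaults
    bounds: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)
    optimizer: OptimizerSettings = field(default_factory=OptimizerSettings)
    ci_level: float = 0.95
    relative_likelihood_threshold: float = 0.147
    ci_grid: int = 200
    ci_expansion: float = 9.0   # search bound = bound ± expansion × (hi − lo)
    na_policy: bool = True
    profile: bool = False    # re-optimize the other parameters at each scan point
    model_options: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.relative_likelihood_threshold <= 1.0:
            raise ConfigurationError("threshold must lie in (0, 1]")


@dataclass
class ConfidenceInterval:
    lower: float
    upper: float
    best: float          # NaN when the NA policy fires
    reliable: bool


@dataclass
class FitResult:
    model: str
    curve_id: str
    params: dict                      # raw best-fit values (all parameters)
    fit_params: list[str]
    intervals: dict                   # name -> ConfidenceInterval
    per_point: pd.DataFrame
    rmse: float
    sigma: float
    nll: float
    aic: float
    n_points: int
    converged: bool
    seed: int

    @property
    def reported_params(self) -> dict:
        """Best-fit values with the NA policy applied."""
        out = dict(self.params)
        for name, ci in self.intervals.items():
            out[name] = ci.best
        return out

    def parameter_table(self) -> pd.DataFrame:
        rows = [
            {"param": n, "best": ci.best, "lower": ci.lower,
             "upper": ci.upper, "reliable": ci.reliable}
            for n, ci in self.intervals.items()
        ]
        return pd.DataFrame(rows)


def rmse(observed, modelled) -> float:
    """Root mean square error between observed and modelled An."""
    observed = np.asarray(observed, float)
    modelled = np.asarray(modelled, float)
    if observed.shape != modelled.shape:
        raise AcifitError(
            f"length mismatch: {observed.shape} observed vs {modelled.shape} modelled"
        )
    if observed.size < 1:
        raise AcifitError("rmse needs at least one point")
    return float(np.sqrt(np.mean((observed - modelled) ** 2)))


def negative_log_likelihood(observed, modelled, sigma) -> float:
    """Gaussian iid NLL; argmin over parameters is σ-independent."""
    if sigma <= 0:
        raise DomainError("sigma must be positive")
    observed = np.asarray(observed, float)
    modelled = np.asarray(modelled, float)
    n = observed.size
    ssr = float(np.sum((observed - modelled) ** 2))
    return n * (math.log(sigma) + LOG_SQRT_2PI) + ssr / (2.0 * sigma**2)


def aic(fit: FitResult) -> float:
    """Akaike information criterion, 2k + 2·NLL with σ counted in k."""
    k = len(fit.fit_params) + 1
    return 2.0 * k + 2.0 * fit.nll


# ---------------------------------------------------------------------------
# model adapters
# ---------------------------------------------------------------------------


class _ModelAdapter:
    """Maps a named parameter vector onto vectorized An predictions."""

    name: str
    param_names: list[str]
    default_fit: list[str]
    default_bounds: dict
    default_preset: str

    def prepare(self, curve: ResponseCurveTable) -> dict:
        arrays = {"Ci": curve.column("Ci"), "An_obs": curve.column("An")}
        for col in ("Qin", "Tleaf"):
            if col in curve.df.columns:
                arrays[col] = curve.column(col)
        if "phiPSII" in curve.df.columns:
            arrays["phiPSII"] = curve.column("phiPSII")
        return arrays

    def defaults(self, curve: ResponseCurveTable, preset: str | None) -> np.ndarray:
        raise NotImplementedError

    def an_matrix(self, theta: np.ndarray, arrays: dict, options: dict) -> np.ndarray:
        raise NotImplementedError

    def per_point(self, theta: np.ndarray, arrays: dict, options: dict) -> pd.DataFrame:
        raise NotImplementedError


class C3AciAdapter(_ModelAdapter):
    name = "c3_aci"
    param_names = list(c3_model.C3_PARAM_NAMES)
    default_fit = ["alpha_old", "J", "RL", "Tp", "Vcmax"]
    default_bounds = {
        "Vcmax": (0.0, 1000.0), "J": (0.0, 1000.0), "Tp": (0.0, 100.0),
        "RL": (0.0, 100.0), "alpha_old": (0.0, 10.0), "alpha_G": (0.0, 10.0),
        "alpha_S": (0.0, 10.0), "alpha_T": (0.0, 10.0),
        "Gamma_star": (1.0, 200.0), "gmc": (1e-3, 10.0),
    }
    default_preset = "c3_sharkey_2007"

    def defaults(self, curve, preset):
        tleaf = float(np.mean(curve.column("Tleaf")))
        kin = evaluate_preset(preset or self.default_preset, tleaf)
        base = {
            "Vcmax": 100.0, "J": 150.0, "Tp": 10.0, "RL": 1.0,
            "alpha_old": 0.0, "alpha_G": 0.0, "alpha_S": 0.0, "alpha_T": 0.0,
            "Gamma_star": kin.get("Gamma_star", 36.94),
            "gmc": np.inf,
            "Kc": kin.get("Kc", 268.8), "Ko": kin.get("Ko", 163.7), "O": 210.0,
        }
        return np.array([base[n] for n in c3_model.C3_PARAM_NAMES])

    def an_matrix(self, theta, arrays, options):
        return c3_model.c3_an_matrix(theta, arrays["Ci"])

    def per_point(self, theta, arrays, options):
        p = c3_model.C3Params(**dict(zip(self.param_names, theta)))
        res = c3_model.c3_assimilation_at_Ci(arrays["Ci"], p)
        return pd.DataFrame({
            "Ci": arrays["Ci"], "An_obs": arrays["An_obs"],
            "An_fit": res.An, "Ac": res.Ac, "Aj": res.Aj,
            "Ap": np.where(np.isinf(res.Ap), np.nan, res.Ap),
            "Cc": res.Cc, "limiting": res.limiting,
        })


class C3VariableJAdapter(C3AciAdapter):
    name = "c3_variable_j"
    param_names = list(c3_model.C3_PARAM_NAMES) + ["tau"]
    default_fit = ["alpha_old", "J", "RL", "tau", "Tp", "Vcmax"]
    default_bounds = dict(C3AciAdapter.default_bounds, tau=(0.01, 1.0))

    def defaults(self, curve, preset):
        base = super().defaults(curve, preset)
        return np.append(base, 0.45)  # tau

    def _gmc_cc(self, theta2d, arrays):
        i = {n: k for k, n in enumerate(self.param_names)}
        RL = theta2d[:, i["RL"]][:, None]
        gs = theta2d[:, i["Gamma_star"]][:, None]
        tau = theta2d[:, i["tau"]][:, None]
        jf = tau * arrays["Qin"][None, :] * arrays["phiPSII"][None, :]
        gmc, Cc = variable_j._vj_gmc_raw(
            arrays["An_obs"][None, :], arrays["Ci"][None, :], jf, RL, gs
        )
        return gmc, Cc, jf

    def an_matrix(self, theta, arrays, options):
        if "phiPSII" not in arrays:
            raise AcifitError("Variable-J fitting requires a phiPSII column")
        gmc, Cc, _ = self._gmc_cc(theta, arrays)
        theta13 = theta[:, :13]
        cols = [theta13[:, k][:, None] for k in range(13)]
        (Vcmax, J, Tp, RL, a_old, a_G, a_S, a_T, gs, _, Kc, Ko, O) = cols
        cj, cp = c3_model.tpu_coefficients(a_old, a_G, a_S, a_T)
        with np.errstate(invalid="ignore", divide="ignore"):
            bad = ~np.isfinite(Cc) | (Cc <= 0)
            Cc_safe = np.where(bad, 1.0, Cc)
            Wc, Wj, Wp = c3_model._rates_raw(Cc_safe, Vcmax, J, Tp, gs, Kc, Ko, O, cj, cp)
            W = np.minimum(np.minimum(Wc, Wj), Wp)
            An = (1.0 - gs / Cc_safe) * W - RL
        return np.where(bad, np.nan, An)

    def per_point(self, theta, arrays, options):
        gmc, Cc, jf = self._gmc_cc(theta[None, :], arrays)
        gmc, Cc, jf = gmc[0], Cc[0], jf[0]
        i = {n: k for k, n in enumerate(self.param_names)}
        p = c3_model.C3Params(**dict(zip(c3_model.C3_PARAM_NAMES, theta[:13])))
        res = c3_model.c3_assimilation_at_Cc(Cc, p)
        jact = variable_j.j_actual(arrays["An_obs"], theta[i["RL"]],
                                   theta[i["Gamma_star"]], Cc)
        return pd.DataFrame({
            "Ci": arrays["Ci"], "An_obs": arrays["An_obs"],
            "An_fit": res.An, "Ac": res.Ac, "Aj": res.Aj,
            "Ap": np.where(np.isinf(res.Ap), np.nan, res.Ap),
            "Cc": Cc, "gmc": gmc, "Jactual": jact, "JF": jf,
            "J": theta[i["J"]], "limiting": res.limiting,
        })


class C4AciAdapter(_ModelAdapter):
    name = "c4_aci"
    param_names = list(c4_model.C4_PARAM_NAMES)
    default_fit = ["RL", "Vcmax", "Vpmax"]
    default_bounds = {
        "Vcmax": (0.0, 500.0), "Vpmax": (0.0, 1000.0), "Vpr": (0.0, 500.0),
        "J": (0.0, 2000.0), "RL": (0.0, 50.0), "fRLm": (0.0, 1.0),
        "gbs": (1e-4, 1.0), "alpha_PSII": (0.0, 1.0),
    }
    default_preset = "c4_von_caemmerer"

    def defaults(self, curve, preset):
        tleaf = float(np.mean(curve.column("Tleaf")))
        kin = evaluate_preset(preset or self.default_preset, tleaf)
        p = c4_model.C4Params(
            Kp=kin.get("Kp", 80.0), Kc=kin.get("Kc", 650.0),
            Ko=kin.get("Ko", 450.0), gamma_star=kin.get("gamma_star", 0.000193),
        )
        return np.array([getattr(p, n) for n in self.param_names])

    def an_matrix(self, theta, arrays, options):
        assumption = options.get("assumption", "rubisco")
        return c4_model.c4_an_matrix(theta, arrays["Ci"], assumption)

    def per_point(self, theta, arrays, options):
        assumption = options.get("assumption", "rubisco")
        p = c4_model.C4Params(**dict(zip(self.param_names, theta)))
        res = c4_model.c4_assimilation(arrays["Ci"], p, assumption)
        return pd.DataFrame({
            "Ci": arrays["Ci"], "An_obs": arrays["An_obs"], "An_fit": res.An,
            "Ac": res.Ac, "Aj": np.where(np.isinf(res.Aj), np.nan, res.Aj),
            "Apc": res.Apc, "Apr": res.Apr, "Ar": res.Ar,
            "limiting": res.limiting, "enzyme_limiting": res.enzyme_limiting,
        })


class C4HyperbolaAdapter(_ModelAdapter):
    name = "c4_hyperbola"
    param_names = ["Vmax", "initial_slope", "curvature", "RL"]
    default_fit = ["Vmax", "initial_slope", "curvature", "RL"]
    default_bounds = {
        "Vmax": (0.0, 500.0), "initial_slope": (0.0, 5.0),
        "curvature": (1e-6, 1.0), "RL": (0.0, 50.0),
    }
    default_preset = "none"

    def defaults(self, curve, preset):
        return np.array([50.0, 0.5, 0.7, 1.0])

    def an_matrix(self, theta, arrays, options):
        return c4_model.hyperbola_an_matrix(theta, arrays["Ci"])

    def per_point(self, theta, arrays, options):
        h = c4_model.HyperbolaParams(*theta)
        an = c4_model.c4_hyperbola(arrays["Ci"], h)
        return pd.DataFrame({
            "Ci": arrays["Ci"], "An_obs": arrays["An_obs"], "An_fit": an,
        })


MODELS = {a.name: a for a in (
    C3AciAdapter(), C3VariableJAdapter(), C4AciAdapter(), C4HyperbolaAdapter()
)}


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _make_nll(adapter, arrays, options, full0, fit_idx, sigma):
    """Batchable NLL over the fitted subset; invalid rows get PENALTY_NLL."""
    obs = arrays["An_obs"]
    n = obs.size
    const = n * (math.log(sigma) + LOG_SQRT_2PI)
    two_s2 = 2.0 * sigma**2

    def nll_rows(pts):
        """pts: (S, n_fit) sample rows -> (S,) NLL values."""
        pts = np.atleast_2d(np.asarray(pts, float))
        full = np.tile(full0, (pts.shape[0], 1))
        full[:, fit_idx] = pts
        an = adapter.an_matrix(full, arrays, options)
        resid = an - obs[None, :]
        with np.errstate(invalid="ignore"):
            ssr = np.sum(resid * resid, axis=1)
        out = const + ssr / two_s2
        return np.where(np.isfinite(out), out, PENALTY_NLL)

    def nll(x):
        """scipy-facing: scalar vector (P,) or vectorized batch (P, S)."""
        x = np.asarray(x, float)
        if x.ndim == 1:
            return float(nll_rows(x[None, :])[0])
        return nll_rows(x.T)

    nll.rows = nll_rows
    return nll


def likelihood_ratio_interval(
    nll,
    best_value: float,
    best_nll: float,
    threshold: float = 0.147,
    search_lower: float = -np.inf,
    search_upper: float = np.inf,
    grid: int = 200,
    rel_tol: float = 1e-6,
    na_policy: bool = True,
) -> ConfidenceInterval:
    """One-parameter likelihood-ratio interval around ``best_value``.

    ``nll`` maps an array of parameter values to NLL values (all other
    parameters held fixed).  The interval is the contiguous region
    around the best fit where L/Lmax ≥ threshold; endpoints are refined
    by bisection to a relative tolerance.  A side that never drops
    below the threshold before its search bound is reported infinite;
    an infinite upper side marks the estimate unreliable (NA).
    """
    log_cut = -math.log(threshold)  # interval: nll - best_nll <= log_cut

    def above(vals):
        return np.asarray(nll(np.asarray(vals, float))) - best_nll <= log_cut

    def find_edge(target_bound):
        if target_bound == best_value:
            return best_value
        vals = np.linspace(best_value, target_bound, grid + 1)[1:]
        ok = above(vals)
        if ok.all():
            return math.copysign(np.inf, target_bound - best_value)
        k = int(np.argmin(ok))  # first grid point outside the region
        inside = best_value if k == 0 else vals[k - 1]
        outside = vals[k]
        while abs(outside - inside) > rel_tol * max(1.0, abs(inside)):
            mid = 0.5 * (inside + outside)
            if above([mid])[0]:
                inside = mid
            else:
                outside = mid
        return inside

    lower = find_edge(search_lower)
    upper = find_edge(search_upper)
    reliable = bool(np.isfinite(upper))
    best = best_value if (reliable or not na_policy) else math.nan
    return ConfidenceInterval(lower=lower, upper=upper, best=best, reliable=reliable)


def _profiled_nll_1d(nll_fun, x_best, k, bounds):
    """Profile likelihood along parameter ``k``: the others re-optimized.

    Warm-starts each inner simplex from the previous solution so the
    scan walks smoothly away from the joint optimum.
    """
    other = [j for j in range(len(x_best)) if j != k]
    other_bounds = [bounds[j] for j in other]
    state = {"x": x_best[other].copy()}

    def nll_1d(vals):
        vals = np.atleast_1d(np.asarray(vals, float))
        out = np.empty(vals.size)
        for i, v in enumerate(vals):
            def inner(xo):
                pt = np.empty(len(x_best))
                pt[other] = xo
                pt[k] = v
                return float(nll_fun.rows(pt[None, :])[0])

            res = minimize(
                inner, state["x"], method="Nelder-Mead", bounds=other_bounds,
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 1500},
            )
            state["x"] = res.x
            out[i] = res.fun
        return out

    return nll_1d


def _widen_interval_by_profiling(
    nll_prof, best, best_nll, plain_ci, threshold,
    search_lower, search_upper, na_policy=True, rel_tol=1e-6,
) -> ConfidenceInterval:
    """Extend a one-at-a-time interval to the profile-likelihood interval.

    The profiled NLL is pointwise no larger than the fixed-others scan,
    so the profiled region contains the plain interval; each side is
    found by an expanding walk outward from the plain edge followed by
    bisection.
    """
    log_cut = -math.log(threshold)

    def above(v):
        return float(nll_prof([v])[0]) - best_nll <= log_cut

    def edge(plain_edge, bound):
        if not np.isfinite(plain_edge):
            return plain_edge
        direction = math.copysign(1.0, bound - best) if bound != best else 0.0
        if direction == 0.0:
            return best
        inside = plain_edge
        step = max(abs(plain_edge - best), 1e-6 * max(1.0, abs(best)))
        outside = None
        while outside is None:
            cand = inside + direction * step
            if (cand - bound) * direction >= 0:
                if above(bound):
                    return math.copysign(np.inf, direction)
                outside = bound
            elif above(cand):
                inside = cand
                step *= 2.0
            else:
                outside = cand
        while abs(outside - inside) > rel_tol * max(1.0, abs(inside)):
            mid = 0.5 * (inside + outside)
            if above(mid):
                inside = mid
            else:
                outside = mid
        return inside

    lower = edge(plain_ci.lower, search_lower)
    upper = edge(plain_ci.upper, search_upper)
    reliable = bool(np.isfinite(upper))
    return ConfidenceInterval(
        lower=lower, upper=upper,
        best=best if (reliable or not na_policy) else math.nan,
        reliable=reliable,
    )


def fit_curve(
    curve: ResponseCurveTable,
    model: str,
    config: FitConfig | None = None,
    preset: str | None = None,
) -> FitResult:
    """Fit a response curve by maximum likelihood.

    ``model`` is one of ``c3_aci``, ``c3_variable_j``, ``c4_aci``,
    ``c4_hyperbola``.  The result is deterministic given
    ``config.optimizer.seed``.
    """
    if model not in MODELS:
        raise ConfigurationError(
            f"unknown model {model!r}; available: {sorted(MODELS)}"
        )
    adapter = MODELS[model]
    config = config or FitConfig()
    curve.validate()

    arrays = adapter.prepare(curve)
    options = dict(config.model_options)
    fit_names = list(config.fit_params or adapter.default_fit)
    unknown = [n for n in fit_names if n not in adapter.param_names]
    if unknown:
        raise ConfigurationError(f"unknown fit parameters {unknown} for {model}")
    n_points = arrays["An_obs"].size
    if n_points <= len(fit_names):
        raise AcifitError(
            f"curve {curve.curve_id!r} has {n_points} points but"
            f" {len(fit_names)} fitted parameters"
        )

    full0 = adapter.defaults(curve, preset)
    for name, value in config.fixed.items():
        full0[adapter.param_names.index(name)] = value
    fit_idx = np.array([adapter.param_names.index(n) for n in fit_names])
    bounds = [
        tuple(config.bounds.get(n, adapter.default_bounds.get(n, (0.0, 1e3))))
        for n in fit_names
    ]
    for n, (lo, hi) in zip(fit_names, bounds):
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ConfigurationError(f"bounds for {n!r} must be finite with lo < hi")

    opt = config.optimizer
    nll_stage1 = _make_nll(adapter, arrays, options, full0, fit_idx, sigma=1.0)
    de = differential_evolution(
        nll_stage1, bounds,
        popsize=opt.popsize * max(1, len(fit_names)),
        maxiter=opt.maxiter, tol=opt.tol,
        mutation=opt.mutation, recombination=opt.recombination,
        seed=opt.seed, polish=False, vectorized=True, updating="deferred",
        init="sobol",
    )
    x_best = de.x
    converged = bool(de.success) or de.nit >= opt.maxiter
    if opt.polish:
        res = minimize(
            nll_stage1, x_best, method="Nelder-Mead", bounds=bounds,
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
        )
        if res.fun <= nll_stage1(x_best):
            x_best = res.x

    theta = full0.copy()
    theta[fit_idx] = x_best
    an_best = adapter.an_matrix(theta[None, :], arrays, options)[0]
    fit_rmse = rmse(arrays["An_obs"], an_best)
    sigma = max(fit_rmse, SIGMA_FLOOR)

    nll_fun = _make_nll(adapter, arrays, options, full0, fit_idx, sigma=sigma)
    best_nll = float(nll_fun(x_best))

    intervals = {}
    for k, name in enumerate(fit_names):
        lo, hi = bounds[k]
        span = hi - lo

        def nll_1d(vals, _k=k):
            vals = np.atleast_1d(np.asarray(vals, float))
            pts = np.tile(x_best, (vals.size, 1))
            pts[:, _k] = vals
            return nll_fun.rows(pts)

        ci = likelihood_ratio_interval(
            nll_1d, float(x_best[k]), best_nll,
            threshold=config.relative_likelihood_threshold,
            search_lower=lo - config.ci_expansion * span,
            search_upper=hi + config.ci_expansion * span,
            grid=config.ci_grid,
            na_policy=config.na_policy,
        )
        if config.profile:
            ci = _widen_interval_by_profiling(
                _profiled_nll_1d(nll_fun, x_best, k, bounds),
                float(x_best[k]), best_nll, ci,
                threshold=config.relative_likelihood_threshold,
                search_lower=lo - config.ci_expansion * span,
                search_upper=hi + config.ci_expansion * span,
                na_policy=config.na_policy,
            )
        intervals[name] = ci

    per_point = adapter.per_point(theta, arrays, options)
    result = FitResult(
        model=model,
        curve_id=curve.curve_id,
        params=dict(zip(adapter.param_names, theta)),
        fit_params=fit_names,
        intervals=intervals,
        per_point=per_point,
        rmse=fit_rmse,
        sigma=sigma,
        nll=float(best_nll),
        aic=math.nan,
        n_points=n_points,
        converged=converged,
        seed=opt.seed,
    )
    result.aic = aic(result)
    return result
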