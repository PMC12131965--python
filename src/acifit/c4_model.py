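"""C4 assimilation: mechanistic von Caemmerer model and empirical hyperbola.

The mechanistic model couples a mesophyll CO2-concentrating pump (PEP
carboxylase, rate Vp) to bundle-sheath C3 chemistry through a leaky
bundle-sheath interface of conductance gbs.  Writing the bundle-sheath
CO2 and O2 balances

    Cs = Cm + (Vp − An − RLm)/gbs
    Os = alpha_PSII·An/(0.047·gbs) + Om

and inserting them into the Rubisco-limited (or electron-transport-
limited) bundle-sheath rate yields a quadratic in An; the smaller root
is the physical solution.  The enzyme-limited rate Ac co-limits PEP
carboxylase, PEP regeneration (Vp = min(Cm·Vpmax/(Cm + Kp), Vpr)) and
Rubisco; the light-limited rate Aj partitions total electron transport
J between mesophyll PEP regeneration (fraction x, giving Vp = x·J/2)
and the bundle-sheath C3 cycle ((1 − x)·J), with no PEP-carboxylase
co-limitation, so An = min(Ac, Aj) switches sharply between branches.

The empirical alternative models gross assimilation as a
non-rectangular hyperbola in Ci with plateau Vmax; the maximum net rate
is Amax = Vmax − RL.  Because the mechanistic high-Ci processes are
rarely distinguishable in practice, Vpmax is often estimated from only
the low-Ci points (Ci ≤ 50–60 µmol mol⁻¹), where PEP carboxylase
dominates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError, InfeasibleError
from .gasex_io import ResponseCurveTable, empty_curve_warning

#: ratio of O2 evolution to carbon fixed used in the bundle-sheath O2 balance
_O2_PER_CARBON = 0.047

#: Vcmax value used to make Rubisco non-binding under the "light" assumption
_VCMAX_NONBINDING = 1000.0

C4_ASSUMPTIONS = ("rubisco", "light", "both")


@dataclass
class C4Params:
    """von Caemmerer C4 parameter vector.

    Rates in µmol m⁻² s⁻¹; Kc, Kp in µmol mol⁻¹; Ko and Om in
    mmol mol⁻¹; gbs and gmc in mol m⁻² s⁻¹; gamma_star is half the
    reciprocal Rubisco specificity (dimensionless); x_etr is the
    fraction of electron transport partitioned to PEP regeneration.
    """

    Vcmax: float = 60.0
    Vpmax: float = 120.0
    Vpr: float = 80.0
    J: float = 400.0
    RL: float = 1.0
    fRLm: float = 0.5
    gbs: float = 0.003
    alpha_PSII: float = 0.0
    Kp: float = 80.0
    Kc: float = 650.0
    Ko: float = 450.0
    gamma_star: float = 0.000193
    Om: float = 210.0
    gmc: float = np.inf
    x_etr: float = 0.4

    def __post_init__(self):
        if min(self.Vcmax, self.Vpmax, self.Vpr, self.J, self.RL) < 0:
            raise DomainError("rates must be nonnegative")
        if not 0.0 <= self.fRLm <= 1.0:
            raise DomainError("fRLm must lie in [0, 1]")
        if not self.gbs > 0:
            raise DomainError("gbs must be positive")

    def with_(self, **kwargs) -> "C4Params":
        return replace(self, **kwargs)


@dataclass
class HyperbolaParams:
    """Empirical non-rectangular hyperbola for An(Ci)."""

    Vmax: float
    initial_slope: float
    curvature: float
    RL: float

    def __post_init__(self):
        if self.Vmax <= 0:
            raise DomainError("Vmax must be positive")
        if not 0.0 <= self.curvature <= 1.0:
            raise DomainError("curvature must lie in [0, 1]")

    @property
    def Amax(self) -> float:
        return self.Vmax - self.RL


class C4PointResult(NamedTuple):
    An: np.ndarray
    Ac: np.ndarray       # enzyme-limited (co-limited) rate
    Aj: np.ndarray       # light-limited rate (+inf when disabled)
    Apc: np.ndarray      # PEP-carboxylase asymptote
    Apr: np.ndarray      # PEP-regeneration asymptote
    Ar: np.ndarray       # Rubisco asymptote
    limiting: np.ndarray         # "enzyme" | "light"
    enzyme_limiting: np.ndarray  # smallest asymptote (informational)


def pep_carboxylation_rate(Cm, p: C4Params):
    """PEP carboxylation rate Vp = min(Cm·Vpmax/(Cm + Kp), Vpr)."""
    Cm = np.asarray(Cm, float)
    if np.any(Cm <= 0):
        raise DomainError("Cm must be positive")
    return np.minimum(Cm * p.Vpmax / (Cm + p.Kp), p.Vpr)


def _quad_smaller_root(a, b, c):
    """Smaller real root of a·x² + b·x + c (sign-normalized); NaN if none."""
    sign = np.where(a < 0, -1.0, 1.0)
    a, b, c = a * sign, b * sign, c * sign
    disc = b * b - 4.0 * a * c
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
    return (-b - sq) / (2.0 * a)


def _enzyme_raw(Cm, Vp, Vcmax, RL, fRLm, gbs, alpha, Kc, Ko_u, gstar, Om_u):
    """Enzyme-limited quadratic; NaN where no real root.  Broadcasts."""
    Rm = fRLm * RL
    Kprime = Kc * (1.0 + Om_u / Ko_u)
    supply = Vp - Rm + gbs * Cm
    a = 1.0 - alpha * Kc / (_O2_PER_CARBON * Ko_u)
    b = -(supply + (Vcmax - RL) + gbs * Kprime
          + alpha / _O2_PER_CARBON * (gstar * Vcmax + RL * Kc / Ko_u))
    c = (Vcmax - RL) * supply - gbs * (gstar * Vcmax * Om_u + RL * Kprime)
    return _quad_smaller_root(a, b, c)


def _light_raw(Cm, J, RL, fRLm, gbs, alpha, gstar, Om_u, x):
    """Light-limited quadratic; NaN where no real root.  Broadcasts."""
    Rm = fRLm * RL
    ag = alpha * gstar / _O2_PER_CARBON
    a = 7.0 * ag / 3.0 - 1.0
    b = (J * ((x / 2.0 + 1.0) + ag * (1.0 - x)) / 3.0
         + RL * (7.0 * ag / 3.0 - 1.0) - Rm
         + gbs * (Cm + 7.0 * gstar * Om_u / 3.0))
    c = (J * J * (x * x - x) / 6.0
         + J * ((Cm * gbs - Rm) * (x - 1.0) - gstar * Om_u * gbs * (x - 1.0)
                + 1.5 * RL * x) / 3.0
         + RL * (Cm * gbs + 7.0 * gstar * Om_u * gbs / 3.0 - Rm))
    return _quad_smaller_root(a, b, c)


def c4_enzyme_limited(Cm, p: C4Params):
    """Enzyme-limited (PEPc/PEP-regeneration/Rubisco co-limited) rate Ac."""
    Cm = np.asarray(Cm, float)
    Vp = pep_carboxylation_rate(Cm, p)
    Ac = _enzyme_raw(Cm, Vp, p.Vcmax, p.RL, p.fRLm, p.gbs, p.alpha_PSII,
                     p.Kc, p.Ko * 1e3, p.gamma_star, p.Om * 1e3)
    if np.any(np.isnan(Ac)):
        raise InfeasibleError(
            "enzyme-limited quadratic has no real root"
            f" (Cm={Cm!r}, params={p!r})"
        )
    return Ac


def c4_light_limited(Cm, p: C4Params):
    """Light-limited rate Aj (electron transport partitioned by x_etr)."""
    Cm = np.asarray(Cm, float)
    if np.any(Cm <= 0):
        raise DomainError("Cm must be positive")
    Aj = _light_raw(Cm, p.J, p.RL, p.fRLm, p.gbs, p.alpha_PSII,
                    p.gamma_star, p.Om * 1e3, p.x_etr)
    if np.any(np.isnan(Aj)):
        raise InfeasibleError(
            f"light-limited quadratic has no real root (Cm={Cm!r}, params={p!r})"
        )
    return Aj


def _c4_components(Cm, p: C4Params):
    Vp_m = Cm * p.Vpmax / (Cm + p.Kp)
    Rm = p.fRLm * p.RL
    Apc = Vp_m + p.gbs * Cm - Rm
    Apr = p.Vpr + p.gbs * Cm - Rm
    Ar = np.broadcast_to(p.Vcmax - p.RL, np.shape(Cm)).astype(float)
    return Apc, Apr, Ar


def c4_assimilation(Ci, p: C4Params, assumption: str = "both") -> C4PointResult:
    """Overall C4 rate An = min(Ac, Aj) at intercellular CO2 ``Ci``.

    ``assumption`` selects which high-Ci process binds: ``"rubisco"``
    disables the light branch, ``"light"`` makes Rubisco non-binding
    (Vcmax treated as effectively infinite), ``"both"`` uses the full
    minimum.  With gmc = ∞, Cm = Ci; a finite gmc is resolved through
    the closure Cm = Ci − An/gmc.
    """
    if assumption not in C4_ASSUMPTIONS:
        raise DomainError(f"assumption must be one of {C4_ASSUMPTIONS}")
    Ci = np.asarray(Ci, float)
    if np.any(Ci <= 0):
        raise DomainError("Ci must be positive")

    if np.isinf(p.gmc):
        Cm = Ci
    else:
        Cm = np.array([_solve_cm(float(ci), p, assumption) for ci in np.atleast_1d(Ci)])
        Cm = Cm.reshape(Ci.shape)

    p_eff = p if assumption != "light" else p.with_(Vcmax=_VCMAX_NONBINDING)
    Ac = c4_enzyme_limited(Cm, p_eff)
    if assumption == "rubisco":
        Aj = np.full_like(np.asarray(Ac, float), np.inf)
    else:
        Aj = c4_light_limited(Cm, p)
    An = np.minimum(Ac, Aj)
    limiting = np.where(Ac <= Aj, "enzyme", "light")
    Apc, Apr, Ar = _c4_components(Cm, p)
    sub = np.argmin(np.stack(np.broadcast_arrays(Apc, Apr, Ar)), axis=0)
    enzyme_limiting = np.array(["pep_carboxylase", "pep_regeneration", "rubisco"])[sub]
    return C4PointResult(An, Ac, Aj, Apc, Apr, Ar, limiting, enzyme_limiting)


def _solve_cm(ci: float, p: C4Params, assumption: str) -> float:
    """Resolve Cm = Ci − An/gmc by bracketing on the scalar residual."""
    def resid(cm):
        q = p.with_(gmc=np.inf)
        res = c4_assimilation(np.array([cm]), q, assumption)
        return cm - (ci - float(res.An[0]) / p.gmc)

    lo, hi = 1e-6, ci + p.Vcmax / p.gmc + 10.0
    return brentq(resid, lo, hi, xtol=1e-10)


def c4_hyperbola(Ci, h: HyperbolaParams):
    """Empirical non-rectangular hyperbola: net assimilation at ``Ci``.

    Gross assimilation is the smaller root of
    θ·A² − (s·Ci + Vmax)·A + s·Ci·Vmax = 0; An = A − RL.  θ = 0 is the
    rectangular limit, θ = 1 the Blackman limit min(s·Ci, Vmax).
    """
    Ci = np.asarray(Ci, float)
    if np.any(Ci < 0):
        raise DomainError("Ci must be nonnegative")
    s, vm, th = h.initial_slope, h.Vmax, h.curvature
    lin = s * Ci + vm
    if th == 0.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            gross = np.where(lin > 0, s * Ci * vm / np.where(lin > 0, lin, 1.0), 0.0)
    else:
        disc = lin * lin - 4.0 * th * s * Ci * vm
        gross = (lin - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * th)
    return gross - h.RL


def hyperbola_an_matrix(theta: np.ndarray, Ci: np.ndarray) -> np.ndarray:
    """Vectorized hyperbola over parameter rows [Vmax, slope, curvature, RL]."""
    vm = theta[:, 0][:, None]
    s = theta[:, 1][:, None]
    th = theta[:, 2][:, None]
    RL = theta[:, 3][:, None]
    Ci = Ci[None, :]
    lin = s * Ci + vm
    disc = lin * lin - 4.0 * th * s * Ci * vm
    with np.errstate(divide="ignore", invalid="ignore"):
        quad = (lin - np.sqrt(np.maximum(disc, 0.0))) / (2.0 * th)
        rect = np.where(lin > 0, s * Ci * vm / np.where(lin > 0, lin, 1.0), 0.0)
    gross = np.where(th > 0, quad, rect)
    return gross - RL


C4_PARAM_NAMES = [
    "Vcmax", "Vpmax", "Vpr", "J", "RL", "fRLm", "gbs", "alpha_PSII",
    "Kp", "Kc", "Ko", "gamma_star", "Om", "gmc", "x_etr",
]


def c4_an_matrix(theta: np.ndarray, Ci: np.ndarray, assumption: str = "rubisco"):
    """An for each parameter row (S, 15) at each Ci (N,); NaN-propagating.

    Assumes gmc = ∞ (Cm = Ci), the configuration used for fitting.
    """
    cols = {n: theta[:, i][:, None] for i, n in enumerate(C4_PARAM_NAMES)}
    Cm = Ci[None, :]
    Vp = np.minimum(Cm * cols["Vpmax"] / (Cm + cols["Kp"]), cols["Vpr"])
    Vcmax = cols["Vcmax"] if assumption != "light" else np.full_like(cols["Vcmax"], _VCMAX_NONBINDING)
    Ac = _enzyme_raw(Cm, Vp, Vcmax, cols["RL"], cols["fRLm"], cols["gbs"],
                     cols["alpha_PSII"], cols["Kc"], cols["Ko"] * 1e3,
                     cols["gamma_star"], cols["Om"] * 1e3)
    if assumption == "rubisco":
        return Ac
    Aj = _light_raw(Cm, cols["J"], cols["RL"], cols["fRLm"], cols["gbs"],
                    cols["alpha_PSII"], cols["gamma_star"], cols["Om"] * 1e3,
                    cols["x_etr"])
    return np.minimum(Ac, Aj)


def low_ci_subset(curve: ResponseCurveTable, threshold: float = 60.0) -> ResponseCurveTable:
    """Retain only points with Ci ≤ threshold (for Vpmax estimation)."""
    if len(curve) == 0:
        raise DomainError("curve has no points")
    mask = curve.column("Ci") <= threshold
    out = ResponseCurveTable(
        curve_id=curve.curve_id,
        df=curve.df[mask].reset_index(drop=True),
        units=dict(curve.units),
        source=curve.source,
        warnings=list(curve.warnings),
    )
    if len(out) == 0:
        empty_curve_warning(
            out, f"no points with Ci <= {threshold} in curve {curve.curve_id!r}"
        )
    return out
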