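"""Steady-state C3 (FvCB) assimilation with TPU limitation.

Net assimilation is An = (1 − Γ*/Cc)·V − RL where V is the smallest of
three potential carboxylation rates:

    Wc = Vcmax·Cc / (Cc + Kc·(1 + O/Ko))          (Rubisco)
    Wj = J·Cc / (4·Cc + Γ*·cj)                    (RuBP regeneration)
    Wp = 3·Tp·Cc / (Cc − Γ*·cp)                   (TPU)

With all glycolate-export fractions zero, cj = 8 and cp = 1, recovering
the classic model.  Reverse sensitivity to CO2 (An decreasing with Cc
under TPU limitation) enters through the export parameters: the single
lumped fraction ``alpha_old`` of the classic formulation, or the
glycine/serine/CH2-THF fractions ``alpha_G``/``alpha_S``/``alpha_T`` of
the updated formulation (at most one formulation may be active).  The
coefficients cj and cp are assembled in one place,
:func:`tpu_coefficients`, so the export accounting can be adjusted
without touching the model logic.

Wp is only defined above the biochemistry-based threshold Cc = Γ*·cp;
below it Wp is reported as +∞ so that TPU can never be selected as the
limiting process there.

Fits on a Ci basis use either "apparent" parameters (mesophyll
conductance gmc = ∞, so Cc = Ci) or, with finite gmc, the analytic
solution of the diffusion closure Cc = Ci − An/gmc: each limiting
process yields a quadratic in An whose lower root is taken, and the
minimum-rate process wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

from .errors import DomainError, InfeasibleError

LIMITING_LABELS = np.array(["rubisco", "rubp_regen", "tpu"])


@dataclass
class C3Params:
    """FvCB parameter vector (rates µmol m⁻² s⁻¹, concentrations as mole fractions)."""

    Vcmax: float
    J: float
    Tp: float
    RL: float
    alpha_old: float = 0.0
    alpha_G: float = 0.0
    alpha_S: float = 0.0
    alpha_T: float = 0.0
    Gamma_star: float = 36.94   # µmol mol⁻¹
    gmc: float = np.inf         # mol m⁻² s⁻¹; ∞ → Ci basis ("apparent")
    Kc: float = 268.8           # µmol mol⁻¹
    Ko: float = 163.7           # mmol mol⁻¹
    O: float = 210.0            # mmol mol⁻¹

    def __post_init__(self):
        if min(self.Vcmax, self.J, self.Tp, self.RL) < 0:
            raise DomainError("rates Vcmax, J, Tp, RL must be nonnegative")
        if self.Gamma_star <= 0:
            raise DomainError("Gamma_star must be positive")
        if not (self.gmc > 0):
            raise DomainError("gmc must be positive (or +inf)")
        if self.alpha_old > 0 and (self.alpha_G > 0 or self.alpha_S > 0 or self.alpha_T > 0):
            raise DomainError(
                "at most one TPU formulation may be active:"
                " alpha_old excludes alpha_G/alpha_S/alpha_T"
            )

    def with_(self, **kwargs) -> "C3Params":
        return replace(self, **kwargs)


class C3PointResult(NamedTuple):
    """Per-point model output (arrays broadcast from the input Cc/Ci)."""

    An: np.ndarray
    Ac: np.ndarray
    Aj: np.ndarray
    Ap: np.ndarray      # +inf where TPU is undefined (below threshold)
    Wc: np.ndarray
    Wj: np.ndarray
    Wp: np.ndarray
    Cc: np.ndarray
    limiting: np.ndarray


def tpu_coefficients(alpha_old=0.0, alpha_G=0.0, alpha_S=0.0, alpha_T=0.0):
    """Γ*-multiplying denominator coefficients (cj, cp) for Wj and Wp.

    All-zero exports give the classic (cj, cp) = (8, 1).  ``alpha_old``
    enters only the TPU denominator (cp = 1 + 3·alpha_old); the updated
    glycolate-export fractions raise both coefficients.
    """
    cj = 8.0 + 16.0 * alpha_G + 8.0 * alpha_S + 8.0 * alpha_T
    cp = 1.0 + 3.0 * alpha_old + 3.0 * alpha_G + 6.0 * alpha_S + 8.0 * alpha_T
    return cj, cp


def tpu_threshold(p: C3Params) -> float:
    """Smallest Cc (µmol mol⁻¹) at which a TPU limitation is allowed."""
    _, cp = tpu_coefficients(p.alpha_old, p.alpha_G, p.alpha_S, p.alpha_T)
    return p.Gamma_star * cp


def _rates_raw(Cc, Vcmax, J, Tp, Gamma_star, Kc, Ko, O, cj, cp):
    """Carboxylation rates; broadcasts; Wp = +inf at/below threshold."""
    Km = Kc * (1.0 + O / Ko)
    Wc = Vcmax * Cc / (Cc + Km)
    Wj = J * Cc / (4.0 * Cc + Gamma_star * cj)
    den = Cc - Gamma_star * cp
    with np.errstate(divide="ignore", invalid="ignore"):
        Wp = np.where(den > 0.0, 3.0 * Tp * Cc / np.where(den > 0, den, 1.0), np.inf)
    return Wc, Wj, Wp


def c3_carboxylation_rates(Cc, p: C3Params):
    """Return (Wc, Wj, Wp) at chloroplast CO2 ``Cc`` (µmol mol⁻¹)."""
    Cc = np.asarray(Cc, dtype=float)
    if np.any(Cc <= 0):
        raise DomainError("Cc must be positive")
    cj, cp = tpu_coefficients(p.alpha_old, p.alpha_G, p.alpha_S, p.alpha_T)
    return _rates_raw(Cc, p.Vcmax, p.J, p.Tp, p.Gamma_star, p.Kc, p.Ko, p.O, cj, cp)


def _select_limiting(Wc, Wj, Wp):
    """Argmin over carboxylation rates with tie priority rubisco > rubp_regen > tpu."""
    code = np.zeros(np.broadcast(Wc, Wj, Wp).shape, dtype=int)
    code = np.where(Wj < np.where(code == 0, Wc, Wj), 1, code)
    best = np.where(code == 0, Wc, Wj)
    code = np.where(Wp < best, 2, code)
    return code


def c3_assimilation_at_Cc(Cc, p: C3Params) -> C3PointResult:
    """Evaluate the model at chloroplast CO2 ``Cc``."""
    Cc = np.asarray(Cc, dtype=float)
    Wc, Wj, Wp = c3_carboxylation_rates(Cc, p)
    code = _select_limiting(Wc, Wj, Wp)
    V = np.where(code == 0, Wc, np.where(code == 1, Wj, Wp))
    pre = 1.0 - p.Gamma_star / Cc
    An = pre * V - p.RL
    Ac = pre * Wc - p.RL
    Aj = pre * Wj - p.RL
    with np.errstate(invalid="ignore"):
        Ap = np.where(np.isinf(Wp), np.inf, pre * Wp - p.RL)
    return C3PointResult(An, Ac, Aj, Ap, Wc, Wj, Wp, Cc, LIMITING_LABELS[code])


def _quad_lower_root(a, b, c):
    """Lower root of a·x² + b·x + c with a < 0; NaN when no real root.

    As a → 0⁻ this root tends continuously to the linear solution −c/b.
    """
    disc = b * b - 4.0 * a * c
    with np.errstate(invalid="ignore"):
        sq = np.sqrt(np.where(disc >= 0, disc, np.nan))
    r1 = (-b + sq) / (2.0 * a)
    r2 = (-b - sq) / (2.0 * a)
    return np.minimum(r1, r2)


def _process_quadratic_An(Ci, gmc, RL, Gamma_star, k1, k2, k3):
    """Solve An for one limiting process under the diffusion closure.

    The process rate has the generic form
    ``An = k1·(Cc − Γ*)/(k2·Cc + k3) − RL`` with ``Cc = Ci − An/gmc``;
    eliminating Cc gives a quadratic in An whose lower root is the
    physical solution (the upper root diverges as gmc → ∞).
    """
    a = -k2 / gmc
    b = k2 * Ci + k3 + (k1 - k2 * RL) / gmc
    c = RL * (k2 * Ci + k3) - k1 * (Ci - Gamma_star)
    return _quad_lower_root(a, b, c)


def _ci_branch_solutions(Ci, Vcmax, J, Tp, RL, gs, gmc, Kc, Ko, O, cj, cp):
    """Per-process (Ac, Aj, Ap) on a Ci basis; Ap = +inf below threshold."""
    Km = Kc * (1.0 + O / Ko)
    Ac = _process_quadratic_An(Ci, gmc, RL, gs, Vcmax, 1.0, Km)
    Aj = _process_quadratic_An(Ci, gmc, RL, gs, J, 4.0, gs * cj)
    Ap = _process_quadratic_An(Ci, gmc, RL, gs, 3.0 * Tp, 1.0, -gs * cp)
    with np.errstate(invalid="ignore"):
        Cc_p = Ci - Ap / gmc
        Ap = np.where(np.isnan(Ap) | (Cc_p <= gs * cp), np.inf, Ap)
    return np.broadcast_arrays(Ac, Aj, Ap)


def _ci_select_consistent(Ci, branches, Vcmax, J, Tp, gs, gmc, Kc, Ko, O, cj, cp):
    """Pick the self-consistent branch by the minimal-carboxylation rule.

    Branch b (with solution A_b and Cc_b = Ci − A_b/gmc) is consistent
    when its own carboxylation rate is the smallest of the three
    evaluated at Cc_b.  Selecting by minimal An instead would pick the
    wrong process below the compensation point, where the
    (1 − Γ*/Cc) prefactor is negative.
    """
    Ac, Aj, Ap = branches
    codes = []
    consistent = []
    for A_b in (Ac, Aj, Ap):
        with np.errstate(invalid="ignore"):
            Cc_b = np.where(np.isfinite(A_b), Ci - A_b / gmc, np.nan)
            Cc_safe = np.where(Cc_b > 0, Cc_b, np.nan)
        Wc, Wj, Wp = _rates_raw(Cc_safe, Vcmax, J, Tp, gs, Kc, Ko, O, cj, cp)
        codes.append(_select_limiting(Wc, Wj, Wp))
        consistent.append(np.isfinite(Cc_safe))
    code = np.full(np.shape(Ac), -1, dtype=int)
    for b in (2, 1, 0):  # later writes win: priority rubisco > rubp > tpu
        ok = consistent[b] & (codes[b] == b)
        code = np.where(ok, b, code)
    # numerical corner: no branch self-consistent -> fall back to min-A
    fallback = _select_limiting(Ac, Aj, Ap)
    return np.where(code < 0, fallback, code)


def _c3_at_Ci_finite_gmc(Ci, p: C3Params, raise_on_infeasible=True):
    cj, cp = tpu_coefficients(p.alpha_old, p.alpha_G, p.alpha_S, p.alpha_T)
    g, gs, RL = p.gmc, p.Gamma_star, p.RL

    Ac, Aj, Ap = _ci_branch_solutions(
        Ci, p.Vcmax, p.J, p.Tp, RL, gs, g, p.Kc, p.Ko, p.O, cj, cp
    )
    if raise_on_infeasible and (np.any(np.isnan(Ac)) or np.any(np.isnan(Aj))):
        bad = "rubisco" if np.any(np.isnan(Ac)) else "rubp_regen"
        raise InfeasibleError(
            f"no real solution for the {bad} process on a Ci basis"
            f" (gmc={g}, check parameter signs and magnitudes)"
        )
    code = _ci_select_consistent(
        Ci, (Ac, Aj, Ap), p.Vcmax, p.J, p.Tp, gs, g, p.Kc, p.Ko, p.O, cj, cp
    )
    An = np.where(code == 0, Ac, np.where(code == 1, Aj, Ap))
    Cc = Ci - An / g
    Wc, Wj, Wp = _rates_raw(Cc, p.Vcmax, p.J, p.Tp, gs, p.Kc, p.Ko, p.O, cj, cp)
    return C3PointResult(An, Ac, Aj, Ap, Wc, Wj, Wp, Cc, LIMITING_LABELS[code])


def c3_assimilation_at_Ci(Ci, p: C3Params) -> C3PointResult:
    """Evaluate the model at intercellular CO2 ``Ci``.

    With gmc = ∞ this reduces exactly to :func:`c3_assimilation_at_Cc`
    at Cc = Ci ("apparent" parameters); with finite gmc each process is
    solved analytically under the closure Cc = Ci − An/gmc.
    """
    Ci = np.asarray(Ci, dtype=float)
    if np.any(Ci <= 0):
        raise DomainError("Ci must be positive")
    if np.isinf(p.gmc):
        return c3_assimilation_at_Cc(Ci, p)
    return _c3_at_Ci_finite_gmc(Ci, p)


# ---------------------------------------------------------------------------
# Vectorized raw-parameter path used by the fitting machinery.  Parameter
# arrays of shape (S, 1) broadcast against Ci of shape (N,), producing
# (S, N) assimilation matrices; invalid entries become NaN instead of
# raising so that an optimizer can penalize and continue.
# ---------------------------------------------------------------------------

C3_PARAM_NAMES = [
    "Vcmax", "J", "Tp", "RL", "alpha_old", "alpha_G", "alpha_S", "alpha_T",
    "Gamma_star", "gmc", "Kc", "Ko", "O",
]


def c3_an_matrix(theta: np.ndarray, Ci: np.ndarray) -> np.ndarray:
    """An for each parameter row of ``theta`` (S, 13) at each ``Ci`` (N,)."""
    cols = [theta[:, i][:, None] for i in range(theta.shape[1])]
    (Vcmax, J, Tp, RL, a_old, a_G, a_S, a_T, gs, gmc, Kc, Ko, O) = cols
    cj, cp = tpu_coefficients(a_old, a_G, a_S, a_T)
    Ci = Ci[None, :]
    finite_g = np.all(np.isfinite(theta[:, 9]))
    if not finite_g:
        Cc = Ci
        Wc, Wj, Wp = _rates_raw(Cc, Vcmax, J, Tp, gs, Kc, Ko, O, cj, cp)
        W = np.minimum(np.minimum(Wc, Wj), Wp)
        return (1.0 - gs / Cc) * W - RL
    with np.errstate(invalid="ignore", divide="ignore"):
        Ac, Aj, Ap = _ci_branch_solutions(
            Ci, Vcmax, J, Tp, RL, gs, gmc, Kc, Ko, O, cj, cp
        )
        code = _ci_select_consistent(
            Ci, (Ac, Aj, Ap), Vcmax, J, Tp, gs, gmc, Kc, Ko, O, cj, cp
        )
    return np.where(code == 0, Ac, np.where(code == 1, Aj, Ap))
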