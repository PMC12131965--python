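"""Variable-J algebra: electron transport, mesophyll conductance, and Cc
from combined gas exchange and chlorophyll fluorescence.

The actual whole-chain electron transport rate required to support a
given net assimilation rate is

    Jactual = (An + RL)·(4·Cc + 8·Γ*)/(Cc − Γ*),

independent of which process limits assimilation.  Equating it with the
fluorescence estimate JF = τ·Qin·φPSII and using the diffusion relation
Cc = Ci − An/gmc yields a closed-form per-point mesophyll conductance:

    Cc  = Γ*·(JF + 8·(An + RL))/(JF − 4·(An + RL))
    gmc = An/(Ci − Cc).

τ is treated as a single lumped proportionality (absorbing leaf
absorptance and PSII partitioning).  gmc is an "effective" conductance
and may legitimately be negative at low-CO2 points where An < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import SingularityError

#: |denominator| below this fraction of JF is treated as singular
DENOMINATOR_RTOL = 1e-9


@dataclass
class VJPoint:
    """One combined gas-exchange + fluorescence observation."""

    An: float
    Ci: float
    Qin: float
    phiPSII: float
    RL: float
    Gamma_star: float
    tau: float


def j_from_fluorescence(tau, Qin, phiPSII):
    """Fluorescence-based electron transport estimate JF = τ·Qin·φPSII."""
    return np.asarray(tau, float) * np.asarray(Qin, float) * np.asarray(phiPSII, float)


def j_actual(An, RL, Gamma_star, Cc):
    """Electron transport rate implied by gas exchange at chloroplast CO2 ``Cc``."""
    An = np.asarray(An, float)
    Cc = np.asarray(Cc, float)
    if np.any(Cc == Gamma_star):
        raise SingularityError("j_actual is singular at Cc = Gamma_star")
    return (An + RL) * (4.0 * Cc + 8.0 * Gamma_star) / (Cc - Gamma_star)


def variable_j_gmc(An, Ci, Qin, phiPSII, RL, Gamma_star, tau):
    """Per-point (gmc, Cc) from the Variable-J inversion (array-friendly).

    Raises :class:`SingularityError` when JF is too close to
    4·(An + RL) (the pole of the inversion) or when gmc = 0 would leave
    Cc undefined.
    """
    An = np.asarray(An, float)
    Ci = np.asarray(Ci, float)
    jf = j_from_fluorescence(tau, Qin, phiPSII)
    den = jf - 4.0 * (An + RL)
    if np.any(np.abs(den) <= DENOMINATOR_RTOL * np.abs(jf)):
        raise SingularityError(
            "tau*Qin*phiPSII = 4*(An + RL): Variable-J inversion is singular"
        )
    Cc = Gamma_star * (jf + 8.0 * (An + RL)) / den
    diff = Ci - Cc
    if np.any((An == 0) & (diff != 0)):
        raise SingularityError("An = 0 with Ci != Cc implies gmc = 0; Cc undefined")
    gmc = An / diff
    return gmc, Cc


def gmc_variable_j(point: VJPoint):
    """Single-point convenience wrapper returning (gmc, Cc)."""
    gmc, Cc = variable_j_gmc(
        point.An, point.Ci, point.Qin, point.phiPSII,
        point.RL, point.Gamma_star, point.tau,
    )
    return float(gmc), float(Cc)


def _vj_gmc_raw(An, Ci, jf, RL, Gamma_star):
    """NaN-propagating inversion used by the fitting machinery (broadcasts)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        den = jf - 4.0 * (An + RL)
        bad = np.abs(den) <= DENOMINATOR_RTOL * np.abs(jf)
        Cc = Gamma_star * (jf + 8.0 * (An + RL)) / np.where(bad, np.nan, den)
        gmc = An / (Ci - Cc)
    return gmc, Cc
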