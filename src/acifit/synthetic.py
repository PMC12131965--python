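"""Synthetic response curves with known ground truth, and simulation studies.

The generator emulates a CO2-response measurement protocol: the
instrument steps reference CO2 through a set-point schedule (including
mid-curve recovery baselines), the leaf's intercellular CO2 tracks each
set-point with a stomatal drawdown factor, and the logged net
assimilation is the forward model value plus iid Gaussian noise.  For
Variable-J curves, φPSII is generated by inverting the fluorescence
relation JF = τ·Qin·φPSII from the electron transport rate implied by
gas exchange at the true mesophyll conductance, so the Variable-J
inversion recovers the generating gmc exactly on noise-free points.

The study driver fits many replicate curves and summarizes parameter
recovery (bias, estimate RMSE), confidence-interval coverage, and the
rate at which estimates are flagged NA (false negatives when a process
is binding, correct suppression — i.e. false positives if not — when it
is absent).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import c3_model, c4_model, variable_j
from .errors import AcifitError
from .gasex_io import (
    CANONICAL_UNITS,
    ResponseCurveTable,
    SetpointSchedule,
    organize_response_curve_data,
)
from .inference import MODELS, FitConfig, fit_curve
from .temperature import evaluate_preset

#: tobacco-style C3 protocol: low-CO2 ramp, two recovery baselines, high ramp
TOBACCO_SCHEDULE = SetpointSchedule(
    [400, 300, 200, 150, 100, 75, 50, 40, 30, 20, 10,
     400, 400, 500, 600, 800, 1000, 1200, 1500],
    optional_points=frozenset({13}),
    recovery_indices=frozenset({11, 12}),
)

#: soybean-style C3 + fluorescence protocol
SOYBEAN_SCHEDULE = SetpointSchedule(
    [400, 300, 200, 150, 100, 75, 50, 20, 400, 400,
     600, 800, 1000, 1200, 1500, 1800],
    recovery_indices=frozenset({8, 9}),
)

#: maize/sorghum-style C4 protocol
MAIZE_SCHEDULE = SetpointSchedule(
    [400, 300, 200, 120, 70, 30, 10, 400, 400, 500, 600, 800, 1200],
    optional_points=frozenset({9}),
    recovery_indices=frozenset({7, 8}),
)

SCHEDULES = {
    "tobacco": TOBACCO_SCHEDULE,
    "soybean": SOYBEAN_SCHEDULE,
    "maize": MAIZE_SCHEDULE,
}


@dataclass
class SimSpec:
    """Conditions for one simulated-curve ensemble."""

    model: str                       # c3_aci | c3_variable_j | c4_aci | c4_hyperbola
    true_params: dict
    schedule: SetpointSchedule = field(default_factory=lambda: TOBACCO_SCHEDULE)
    noise_sd: float = 0.5            # µmol m⁻² s⁻¹ on An
    phipsii_noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0
    qin: float = 1500.0              # µmol m⁻² s⁻¹
    tleaf: float = 27.0              # °C
    drawdown: float = 0.7            # Ci ≈ drawdown × set-point
    preset: str | None = None
    label: str = ""

    def __post_init__(self):
        if self.noise_sd < 0 or self.n_replicates < 1:
            raise AcifitError("noise_sd must be >= 0 and n_replicates >= 1")
        if self.model not in MODELS:
            raise AcifitError(f"unknown model {self.model!r}")


def _forward_an(spec: SimSpec, Ci: np.ndarray):
    """Noise-free An (and extras) from the true parameter vector."""
    adapter = MODELS[spec.model]
    kin = {}
    if spec.model in ("c3_aci", "c3_variable_j"):
        kin = evaluate_preset(spec.preset or "c3_sharkey_2007", spec.tleaf)
        base = {"Gamma_star": kin["Gamma_star"], "Kc": kin["Kc"], "Ko": kin["Ko"]}
    elif spec.model == "c4_aci":
        kin = evaluate_preset(spec.preset or "c4_von_caemmerer", spec.tleaf)
        base = {"Kp": kin["Kp"], "Kc": kin["Kc"], "Ko": kin["Ko"],
                "gamma_star": kin["gamma_star"]}
    else:
        base = {}

    extras = {}
    if spec.model == "c3_aci":
        p = c3_model.C3Params(**{**base, **spec.true_params})
        an = c3_model.c3_assimilation_at_Ci(Ci, p).An
    elif spec.model == "c3_variable_j":
        tp = dict(spec.true_params)
        tau = tp.pop("tau")
        p = c3_model.C3Params(**{**base, **tp})
        if not np.isfinite(p.gmc):
            raise AcifitError("Variable-J generation needs a finite true gmc")
        res = c3_model.c3_assimilation_at_Ci(Ci, p)
        an = res.An
        jact = variable_j.j_actual(an, p.RL, p.Gamma_star, res.Cc)
        extras["phiPSII"] = jact / (tau * spec.qin)
        extras["Cc"] = res.Cc
    elif spec.model == "c4_aci":
        p = c4_model.C4Params(**{**base, **spec.true_params})
        an = c4_model.c4_assimilation(Ci, p, assumption="both").An
    elif spec.model == "c4_hyperbola":
        h = c4_model.HyperbolaParams(**spec.true_params)
        an = c4_model.c4_hyperbola(Ci, h)
    else:  # pragma: no cover
        raise AcifitError(spec.model)
    return np.asarray(an, float), extras


def generate_curve(spec: SimSpec, replicate_index: int = 0):
    """Generate one replicate curve; returns (table, truth record).

    Deterministic per (spec.seed, replicate_index).
    """
    rng = np.random.default_rng([spec.seed, replicate_index])
    setpoints = np.asarray(spec.schedule.setpoints, float)
    Ci = setpoints * spec.drawdown
    an, extras = _forward_an(spec, Ci)

    keep = np.isfinite(an)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} infeasible point(s) from"
            f" replicate {replicate_index}", stacklevel=2,
        )
    an_noisy = an + rng.normal(0.0, spec.noise_sd, size=an.shape)

    data = {
        "co2_setpoint": setpoints,
        "Ci": Ci,
        "An": an_noisy,
        "Qin": np.full_like(Ci, spec.qin),
        "Tleaf": np.full_like(Ci, spec.tleaf),
    }
    if "phiPSII" in extras:
        phi = extras["phiPSII"]
        if spec.phipsii_noise_sd > 0:
            phi = phi + rng.normal(0.0, spec.phipsii_noise_sd, size=phi.shape)
        data["phiPSII"] = phi
    df = pd.DataFrame(data)[keep].reset_index(drop=True)

    cid = f"{spec.label or spec.model}-{replicate_index}"
    units = {k: CANONICAL_UNITS[k] for k in data}
    table = ResponseCurveTable(curve_id=cid, df=df, units=units, source="synthetic")
    truth = dict(spec.true_params)
    truth["_an_true"] = an[keep]
    return table, truth


def write_instrument_log(table: ResponseCurveTable, path: str | Path) -> None:
    """Write a curve in the two-header-row instrument-log dialect."""
    path = Path(path)
    cols = list(table.df.columns)
    lines = [",".join(cols),
             ",".join(table.units.get(c, "") for c in cols)]
    for _, row in table.df.iterrows():
        cells = []
        for c in cols:
            v = row[c]
            cells.append(f"{v:.9g}" if isinstance(v, (int, float, np.floating)) else str(v))
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def _contains(ci, truth_value) -> bool:
    lo = ci.lower if np.isfinite(ci.lower) else -np.inf
    hi = ci.upper if np.isfinite(ci.upper) else np.inf
    return bool(lo <= truth_value <= hi)


def simulation_study(
    specs: list[SimSpec],
    fit_config: FitConfig | None = None,
    organize: bool = True,
) -> pd.DataFrame:
    """Fit every replicate of every spec; summarize per (spec, parameter).

    Columns: label, param, n, truth, bias, rmse, coverage, na_rate,
    n_failed.  Per-curve failures are logged and skipped, never fatal.
    """
    rows = []
    base_config = fit_config or FitConfig()
    for spec in specs:
        records: dict[str, list] = {}
        intervals: dict[str, list] = {}
        n_failed = 0
        for r in range(spec.n_replicates):
            table, truth = generate_curve(spec, r)
            if organize:
                table = organize_response_curve_data(table, spec.schedule)
            cfg = replace_seed(base_config, (spec.seed * 100003 + r) % 2**31)
            try:
                fit = fit_curve(table, spec.model, cfg, preset=spec.preset)
            except AcifitError as exc:
                warnings.warn(f"fit failed for {table.curve_id}: {exc}", stacklevel=2)
                n_failed += 1
                continue
            for name, ci in fit.intervals.items():
                records.setdefault(name, []).append(fit.params[name])
                intervals.setdefault(name, []).append(ci)
        for name, estimates in records.items():
            truth_value = spec.true_params.get(name)
            cis = intervals[name]
            est = np.asarray(estimates, float)
            row = {
                "label": spec.label or spec.model,
                "param": name,
                "n": len(est),
                "truth": truth_value,
                "na_rate": float(np.mean([not ci.reliable for ci in cis])),
                "n_failed": n_failed,
            }
            if truth_value is not None:
                row["bias"] = float(np.mean(est) - truth_value)
                row["rmse"] = float(np.sqrt(np.mean((est - truth_value) ** 2)))
                row["coverage"] = float(np.mean([
                    _contains(ci, truth_value) for ci in cis
                ]))
            rows.append(row)
    return pd.DataFrame(rows)


def replace_seed(config: FitConfig, seed: int) -> FitConfig:
    """Copy a FitConfig with a different optimizer seed."""
    from dataclasses import replace
    opt = replace(config.optimizer, seed=int(seed))
    return replace(config, optimizer=opt)
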