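"""Temperature responses of kinetic parameters.

Each temperature-dependent parameter is described by a
:class:`TempResponseSpec` giving its value at a reference temperature
(25 °C by default) and a functional form used to scale it to leaf
temperature: an Arrhenius exponential (activation energy in kJ mol⁻¹),
a polynomial in leaf temperature (°C), or a constant.

Preset collections (one YAML file per preset, shipped as editable data)
bundle specs for every parameter a model scales.  Entries named
``<param>_norm`` are dimensionless multipliers applied to fitted rates
(Vcmax, J, ...) rather than absolute values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigurationError

#: gas constant, J mol⁻¹ K⁻¹
R_GAS = 8.314

_FORMS = ("arrhenius", "polynomial", "constant")


@dataclass
class TempResponseSpec:
    """One parameter's temperature response.

    parameters:
        ``arrhenius`` — ``{"activation_energy": Ea}`` in kJ mol⁻¹;
        ``polynomial`` — ``{"coefficients": [c0, c1, ...]}`` evaluated as
        ``c0 + c1·T + c2·T² + ...`` with T in °C (the coefficients carry
        the target parameter's units and should reproduce
        ``reference_value`` at ``reference_temperature``);
        ``constant`` — ignored.
    """

    form: str
    reference_value: float
    parameters: dict = field(default_factory=dict)
    reference_temperature: float = 25.0
    units: str = ""

    def __post_init__(self):
        if self.form not in _FORMS:
            raise ConfigurationError(
                f"unknown temperature-response form {self.form!r};"
                f" expected one of {_FORMS}"
            )
        if self.form == "arrhenius":
            ea = self.parameters.get("activation_energy")
            if ea is None or not np.isfinite(ea):
                raise ConfigurationError(
                    "arrhenius form requires a finite activation_energy"
                )
        if self.form == "polynomial" and not self.parameters.get("coefficients"):
            raise ConfigurationError("polynomial form requires coefficients")


def apply_temp_response(spec: TempResponseSpec, tleaf) -> float | np.ndarray:
    """Scale ``spec.reference_value`` from the reference temperature to ``tleaf`` (°C)."""
    tleaf = np.asarray(tleaf, dtype=float)
    if np.any(tleaf <= -273.15):
        raise ConfigurationError("leaf temperature below absolute zero")
    if spec.form == "constant":
        out = np.broadcast_to(spec.reference_value, tleaf.shape).copy()
    elif spec.form == "arrhenius":
        ea = spec.parameters["activation_energy"] * 1e3  # kJ/mol -> J/mol
        t_ref = spec.reference_temperature + 273.15
        t_k = tleaf + 273.15
        out = spec.reference_value * np.exp(ea / R_GAS * (1.0 / t_ref - 1.0 / t_k))
    elif spec.form == "polynomial":
        coefs = list(spec.parameters["coefficients"])
        out = np.polynomial.polynomial.polyval(tleaf, coefs)
    else:  # pragma: no cover - guarded in __post_init__
        raise ConfigurationError(f"unknown form {spec.form!r}")
    return float(out) if out.ndim == 0 else out


_PRESET_DIR = resources.files("acifit") / "presets"
_RUNTIME_PRESETS: dict[str, dict[str, TempResponseSpec]] = {}


def _load_preset_file(path) -> dict[str, TempResponseSpec]:
    data = yaml.safe_load(Path(str(path)).read_text(encoding="utf-8"))
    out = {}
    for name, entry in data.items():
        out[name] = TempResponseSpec(
            form=entry["form"],
            reference_value=float(entry["reference_value"]),
            parameters=entry.get("parameters", {}) or {},
            reference_temperature=float(entry.get("reference_temperature", 25.0)),
            units=entry.get("units", ""),
        )
    return out


def available_presets() -> list[str]:
    names = {p.name[:-5] for p in Path(str(_PRESET_DIR)).glob("*.yaml")}
    names.update(_RUNTIME_PRESETS)
    return sorted(names)


def get_preset(name: str) -> dict[str, TempResponseSpec]:
    """Return the named preset as a parameter → spec mapping."""
    if name in _RUNTIME_PRESETS:
        return dict(_RUNTIME_PRESETS[name])
    path = Path(str(_PRESET_DIR)) / f"{name}.yaml"
    if not path.exists():
        raise ConfigurationError(
            f"unknown temperature preset {name!r};"
            f" available: {', '.join(available_presets())}"
        )
    return _load_preset_file(path)


def register_preset(name: str, specs: dict[str, TempResponseSpec]) -> None:
    """Register an in-memory preset (overrides files of the same name)."""
    _RUNTIME_PRESETS[name] = dict(specs)


def evaluate_preset(name_or_specs, tleaf) -> dict[str, float]:
    """Evaluate every spec of a preset at ``tleaf`` (°C)."""
    specs = get_preset(name_or_specs) if isinstance(name_or_specs, str) else name_or_specs
    return {k: apply_temp_response(v, tleaf) for k, v in specs.items()}
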