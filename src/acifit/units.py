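"""Unit-string normalization and comparison.

Gas-exchange log files record units as free text that varies across
instrument firmware versions ("µmol m⁻² s⁻¹", "umol m^-2 s^-1", ...).
Columns are compared after a lossy normalization rather than through a
full unit system: case is ignored, the micro sign and "u" are
interchangeable, and the superscript/caret exponent spellings collapse
to a plain "-1" form.
"""

from __future__ import annotations

_SUPERSCRIPTS = str.maketrans({
    "⁻": "-", "⁰": "0", "¹": "1", "²": "2", "³": "3", "⁴": "4",
    "⁵": "5", "⁶": "6", "⁷": "7", "⁸": "8", "⁹": "9",
})


def normalize_unit(unit: str) -> str:
    """Return a canonical form of a unit string for comparison."""
    s = unit.strip().lower()
    s = s.replace("µ", "u").replace("μ", "u")
    s = s.translate(_SUPERSCRIPTS)
    s = s.replace("^", "")
    s = " ".join(s.split())
    return s


def units_equivalent(a: str, b: str) -> bool:
    """True if two unit strings normalize to the same form."""
    return normalize_unit(a) == normalize_unit(b)
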