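"""Reading, validating, and organizing gas-exchange log files.

A portable-photosynthesis-system log is modelled as delimited text with
two header rows: one naming the columns and one giving their units,
followed by one data row per logged point.  Files exported by some
instruments contain several header blocks (remarks, reconfigurations);
the last block is taken as authoritative.  Plain CSV files (single
header row) are supported with units supplied by the caller.

Curves are grouped by an identifier column (default ``curve_id``); a
file lacking it is treated as a single curve named after the file.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    MissingColumnError,
    ParseError,
    ScheduleError,
)
from .units import normalize_unit

#: canonical column names used throughout the package
REQUIRED_COLUMNS = ("An", "Ci", "Qin", "Tleaf")

#: common instrument-log spellings mapped onto canonical names
COLUMN_ALIASES = {
    "A": "An",
    "PhiPS2": "phiPSII",
    "phiPS2": "phiPSII",
    "PhiPSII": "phiPSII",
    "CO2_r_sp": "co2_setpoint",
    "CO2_sp": "co2_setpoint",
    "Pa": "pressure",
    "Press": "pressure",
    "TleafCnd": "Tleaf",
}

#: units used when the package writes logs itself
CANONICAL_UNITS = {
    "co2_setpoint": "µmol mol⁻¹",
    "Ci": "µmol mol⁻¹",
    "Ca": "µmol mol⁻¹",
    "An": "µmol m⁻² s⁻¹",
    "Qin": "µmol m⁻² s⁻¹",
    "Tleaf": "°C",
    "phiPSII": "dimensionless",
    "pressure": "kPa",
}


@dataclass
class ResponseCurveTable:
    """One CO2-response curve: per-point measurements plus units metadata.

    ``df`` holds one row per logged point in measurement order.  ``units``
    maps canonical column names to the unit strings found in (or written
    to) the log file, recorded verbatim.
    """

    curve_id: str
    df: pd.DataFrame
    units: dict[str, str]
    source: str = "synthetic"
    warnings: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.df)

    def validate(self) -> None:
        """Check structural invariants; raise on violation."""
        if len(self.df) < 1:
            raise EmptyInputError(f"curve {self.curve_id!r} has no points")
        for col in REQUIRED_COLUMNS:
            if col not in self.df.columns:
                raise MissingColumnError(col, self.source)
        for col in ("Ci", "Qin", "An"):
            vals = self.df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                row = int(np.flatnonzero(~np.isfinite(vals))[0])
                raise ParseError(
                    f"non-finite value in column {col!r} at data row {row}"
                    f" of curve {self.curve_id!r}",
                    row=row, column=col,
                )

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy(dtype=float)


@dataclass
class SetpointSchedule:
    """The nominal sequence of reference-CO2 set-points for a protocol.

    ``optional_points`` are schedule positions that may be absent from a
    given curve; ``recovery_indices`` are repeated-baseline positions
    (re-equilibration after the low-CO2 ramp) dropped before fitting.
    """

    setpoints: list[float]
    optional_points: frozenset[int] = frozenset()
    recovery_indices: frozenset[int] = frozenset()

    def __post_init__(self):
        if not self.setpoints:
            raise ScheduleError("schedule has no set-points")
        self.optional_points = frozenset(self.optional_points)
        self.recovery_indices = frozenset(self.recovery_indices)
        n = len(self.setpoints)
        bad = [i for i in self.recovery_indices if not 0 <= i < n]
        if bad:
            raise ScheduleError(f"recovery indices {bad} out of range 0..{n - 1}")


@dataclass
class ValidationReport:
    passed: bool
    messages: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def _looks_like_header(cells: list[str]) -> bool:
    names = {c.strip() for c in cells}
    canon = {COLUMN_ALIASES.get(n, n) for n in names}
    return "Ci" in canon and "An" in canon


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _coerce_columns(df: pd.DataFrame, path: str) -> pd.DataFrame:
    """Parse numeric columns, locating any bad cell; leave pure-text columns."""
    out = {}
    for col in df.columns:
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = num.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            if num.notna().any() or col in REQUIRED_COLUMNS:
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ParseError(
                    f"unparseable numeric value {raw.iloc[row]!r} in column"
                    f" {col!r}, data row {row} of {path}",
                    row=row, column=col,
                )
            out[col] = raw  # pure text column (e.g. curve identifier)
        else:
            out[col] = num
    return pd.DataFrame(out)


def read_gasex_file(
    path: str | Path,
    dialect: str = "instrument-log",
    units: dict[str, str] | None = None,
    curve_id_column: str = "curve_id",
) -> list[ResponseCurveTable]:
    """Read a gas-exchange log into one or more :class:`ResponseCurveTable`.

    Parameters
    ----------
    path
        Delimited text file (comma or tab, auto-detected).
    dialect
        ``"instrument-log"`` expects a column-name row followed by a units
        row; ``"plain-csv"`` expects a single header row with units given
        through ``units``.
    units
        Column → unit-string mapping for the plain-csv dialect.
    curve_id_column
        Column used to split the file into curves.  Absent → one curve
        named after the file stem.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise EmptyInputError(f"{path} is empty")

    if dialect == "instrument-log":
        delim = None
        header_idx = None
        for i, ln in enumerate(lines):
            d = _detect_delimiter(ln)
            if _looks_like_header(ln.split(d)):
                header_idx, delim = i, d  # keep last matching block
        if header_idx is None:
            raise ParseError(f"no header row naming An/Ci columns found in {path}")
        if header_idx + 1 >= len(lines):
            raise EmptyInputError(f"{path} has a header but no units row or data")
        names = [c.strip() for c in lines[header_idx].split(delim)]
        unit_cells = [c.strip() for c in lines[header_idx + 1].split(delim)]
        data_lines = lines[header_idx + 2:]
        if not data_lines:
            raise EmptyInputError(f"{path} has headers but no data rows")
        df = pd.read_csv(
            io.StringIO("\n".join(data_lines)),
            sep=delim, header=None, names=names, dtype=str,
            skipinitialspace=True,
        )
        file_units = dict(zip(names, unit_cells))
    elif dialect == "plain-csv":
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
        if len(df) == 0:
            raise EmptyInputError(f"{path} has no data rows")
        file_units = dict(units or {})
    else:
        raise ParseError(f"unknown dialect {dialect!r}")

    df = df.rename(columns=COLUMN_ALIASES)
    file_units = {COLUMN_ALIASES.get(k, k): v for k, v in file_units.items()}
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise MissingColumnError(col, str(path))
    df = _coerce_columns(df, str(path))

    tables = []
    if curve_id_column in df.columns:
        groups = [(str(cid), g) for cid, g in df.groupby(curve_id_column, sort=False)]
    else:
        groups = [(path.stem, df)]
    for cid, g in groups:
        tab = ResponseCurveTable(
            curve_id=cid,
            df=g.reset_index(drop=True),
            units=dict(file_units),
            source=str(path),
        )
        tab.validate()
        tables.append(tab)
    return tables


def validate_units(
    table: ResponseCurveTable, expected: dict[str, str]
) -> ValidationReport:
    """Check that every expected column is present with an equivalent unit."""
    messages = []
    for col, unit in expected.items():
        if col not in table.units:
            messages.append(f"column {col!r}: missing (expected {unit!r})")
        elif normalize_unit(table.units[col]) != normalize_unit(unit):
            messages.append(
                f"column {col!r}: unit {table.units[col]!r} does not match"
                f" expected {unit!r}"
            )
    return ValidationReport(passed=not messages, messages=messages)


def _align_to_schedule(
    setpoints: np.ndarray, schedule: SetpointSchedule, tol: float
) -> tuple[dict[int, int], list[str]]:
    """Map curve rows onto schedule positions.

    Returns (row → schedule index, mismatch messages).  Absences are
    tolerated only at optional schedule positions.
    """
    mapping: dict[int, int] = {}
    mismatches: list[str] = []
    i = 0
    n = len(setpoints)
    for j, sp in enumerate(schedule.setpoints):
        if i < n and abs(setpoints[i] - sp) <= tol:
            mapping[i] = j
            i += 1
        elif j in schedule.optional_points:
            continue
        else:
            got = f"{setpoints[i]:g}" if i < n else "nothing"
            mismatches.append(
                f"position {j}: expected set-point {sp:g}, found {got}"
            )
            if i < n:
                i += 1
    for k in range(i, n):
        mismatches.append(f"extra point with set-point {setpoints[k]:g} (row {k})")
    return mapping, mismatches


def check_response_curve_data(
    tables: list[ResponseCurveTable],
    schedule: SetpointSchedule,
    tol: float = 1.0,
) -> ValidationReport:
    """Verify that every curve follows the same set-point schedule.

    ``tol`` is the allowed deviation between a logged set-point and its
    nominal value, in µmol mol⁻¹.
    """
    messages = []
    for tab in tables:
        if "co2_setpoint" not in tab.df.columns:
            messages.append(f"curve {tab.curve_id!r}: no co2_setpoint column")
            continue
        _, mm = _align_to_schedule(tab.column("co2_setpoint"), schedule, tol)
        messages.extend(f"curve {tab.curve_id!r}: {m}" for m in mm)
    return ValidationReport(passed=not messages, messages=messages)


def organize_response_curve_data(
    table: ResponseCurveTable,
    schedule: SetpointSchedule,
    ordering: str = "measured",
    tol: float = 1.0,
) -> ResponseCurveTable:
    """Drop recovery points and optionally sort the curve by Ci.

    Retained rows are carried through unchanged.  ``ordering`` is either
    ``"measured"`` (keep logging order) or ``"ascending-Ci"``.
    """
    if ordering not in ("measured", "ascending-Ci"):
        raise ScheduleError(f"unknown ordering {ordering!r}")
    mapping, _ = _align_to_schedule(table.column("co2_setpoint"), schedule, tol)
    keep = [
        r for r in range(len(table.df))
        if mapping.get(r, -1) not in schedule.recovery_indices
    ]
    df = table.df.iloc[keep].reset_index(drop=True)
    if ordering == "ascending-Ci":
        df = df.sort_values("Ci", kind="stable").reset_index(drop=True)
    return ResponseCurveTable(
        curve_id=table.curve_id,
        df=df,
        units=dict(table.units),
        source=table.source,
        warnings=list(table.warnings),
    )


def write_tidy_csv(tables: list[ResponseCurveTable], path: str | Path) -> None:
    """Write organized curves as tidy CSV (one row per retained point)."""
    frames = []
    for tab in tables:
        df = tab.df.copy()
        df.insert(0, "curve_id", tab.curve_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def empty_curve_warning(table: ResponseCurveTable, message: str) -> ResponseCurveTable:
    """Attach a warning to a (possibly empty) curve and emit it."""
    warnings.warn(message, stacklevel=2)
    table.warnings.append(message)
    return table
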