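"""Plain-text serialization: traces, measurements, reports.

Trace files are TSV with a '#'-prefixed ``key=value`` metadata header —
greppable, spreadsheet-safe, and round-trips floats at full precision.
Measurement files are delimited text with a header-name row, a units
row, and one value row (the shape of a summary measurement table).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd

from .estimator import MEASUREMENT_FIELDS, UssingMeasurement
from .model import InvalidInputError, SecretionTrace

__all__ = [
    "write_trace",
    "read_trace",
    "write_measurement",
    "read_measurement",
    "write_report",
]

TRACE_COLUMNS = (
    "time_s",
    "cl_in_mM",
    "i_apical_uApercm2",
    "i_basolateral_uApercm2",
    "i_uptake_uApercm2",
)

_MEASUREMENT_UNITS = ("uA/cm2", "uA/cm2", "uS", "uS", "uS", "uS")


def _parse_meta_value(raw: str):
    import ast

    raw = raw.strip()
    try:
        return ast.literal_eval(raw)
    except (ValueError, SyntaxError):
        pass
    try:
        return float(raw)
    except ValueError:
        return raw


def write_trace(path: str | Path, trace: SecretionTrace, metadata: dict | None = None) -> None:
    """Write a trace as TSV with a metadata header block."""
    lines = []
    for k, v in (metadata or {}).items():
        lines.append(f"# {k}={v!r}" if isinstance(v, str) else f"# {k}={v}")
    lines.append("\t".join(TRACE_COLUMNS))
    cols = (trace.t, trace.cl_in, trace.i_apical, trace.i_basolateral, trace.i_uptake)
    for row in zip(*cols):
        lines.append("\t".join(format(x, ".17g") for x in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace(path: str | Path) -> tuple[SecretionTrace, dict]:
    """Read a trace file back; returns (trace, metadata)."""
    metadata: dict = {}
    body_lines = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            metadata[key.strip()] = _parse_meta_value(value)
        elif line.strip():
            body_lines.append(line)
    df = pd.read_csv(
        _io.StringIO("\n".join(body_lines)), sep="\t", float_precision="round_trip"
    )
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidInputError(f"trace file missing columns: {sorted(missing)}")
    trace = SecretionTrace(
        t=df["time_s"].to_numpy(),
        cl_in=df["cl_in_mM"].to_numpy(),
        i_apical=df["i_apical_uApercm2"].to_numpy(),
        i_basolateral=df["i_basolateral_uApercm2"].to_numpy(),
        i_uptake=df["i_uptake_uApercm2"].to_numpy(),
    )
    return trace, metadata


def write_measurement(path: str | Path, m: UssingMeasurement, sep: str = "\t") -> None:
    """Write the six measurables with a header row and a units row."""
    rows = [
        sep.join(MEASUREMENT_FIELDS),
        sep.join(_MEASUREMENT_UNITS),
        sep.join(format(getattr(m, f), ".17g") for f in MEASUREMENT_FIELDS),
    ]
    Path(path).write_text("\n".join(rows) + "\n")


def read_measurement(path: str | Path) -> UssingMeasurement:
    """Parse a delimited measurement file (header names, units row,
    value row) into an :class:`UssingMeasurement`."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in MEASUREMENT_FIELDS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"measurement file missing column(s): {missing}")
    # drop the units row (non-numeric) if present
    values = None
    for _, row in df.iterrows():
        try:
            values = {f: float(row[f]) for f in MEASUREMENT_FIELDS}
            break
        except (TypeError, ValueError):
            continue
    if values is None:
        raise InvalidInputError("measurement file contains no numeric value row")
    return UssingMeasurement(**values)


def write_report(path: str | Path, values: dict, header: str = "") -> None:
    """Write a machine-readable key=value report with an optional
    human-readable header (comment lines)."""
    lines = [f"# {line}" for line in header.splitlines() if line]
    lines += [f"{k}={v}" for k, v in values.items()]
    Path(path).write_text("\n".join(lines) + "\n")
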