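"""CSV dialects: scan curves, reading tables, k-factor and ROF tables.

Scan files are plain CSV with ``#key=value`` comment header lines carrying
the acquisition metadata (``scan_type``, ``cone_mm``, ``ssd_mm``,
``depth_mm``, ``detector``, ``tilt_deg``; extra keys round-trip), followed by
a ``position_mm,value`` column header and data rows.  Floats are written with
``repr`` so that write -> read -> write is byte-identical.

Tabular files (readings, corrections, references, ROF tables) are ordinary
header+rows CSV, optionally preceded by ``#key=value`` provenance comments
(seed, config hash), read with pandas.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .scan_analysis import ScanCurve

__all__ = [
    "read_scan_csv",
    "write_scan_csv",
    "write_table_csv",
    "read_table_csv",
    "READING_COLUMNS",
]

_REQUIRED_KEYS = ("scan_type", "cone_mm", "ssd_mm")
_FLOAT_KEYS = ("cone_mm", "ssd_mm", "depth_mm", "tilt_deg")

#: Column schema of detector reading tables.
READING_COLUMNS = ("detector", "cone_mm", "ssd_mm", "depth_mm", "value", "sigma")


def _format_value(v) -> str:
    if isinstance(v, float):
        return repr(v)
    return str(v)


def write_scan_csv(curve: ScanCurve, path) -> None:
    """Write a scan curve in the documented dialect (lossless round-trip)."""
    lines = []
    meta = dict(curve.metadata)
    for key in ("scan_type", "cone_mm", "ssd_mm", "depth_mm", "detector", "tilt_deg"):
        if key in meta:
            lines.append(f"#{key}={_format_value(meta.pop(key))}")
    for key in sorted(meta):
        lines.append(f"#{key}={_format_value(meta[key])}")
    lines.append("position_mm,value")
    for p, v in zip(curve.positions, curve.values):
        lines.append(f"{p!r},{v!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_scan_csv(path) -> ScanCurve:
    """Parse a scan-CSV file; malformed input raises ParseError with a line."""
    text = Path(path).read_text()
    metadata = {}
    positions = []
    values = []
    saw_header = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if saw_header:
                raise ParseError("metadata after column header", line=lineno)
            if "=" not in line:
                raise ParseError(f"malformed metadata line {line!r}", line=lineno)
            key, _, val = line[1:].partition("=")
            key = key.strip()
            val = val.strip()
            if key in _FLOAT_KEYS and val != "":
                try:
                    val = float(val)
                except ValueError:
                    raise ParseError(
                        f"non-numeric value for {key!r}: {val!r}", line=lineno
                    ) from None
            metadata[key] = val
            continue
        if not saw_header:
            if line != "position_mm,value":
                raise ParseError(
                    f"expected 'position_mm,value' column header, got {line!r}",
                    line=lineno,
                )
            saw_header = True
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise ParseError(f"expected two columns, got {line!r}", line=lineno)
        try:
            positions.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError:
            raise ParseError(f"non-numeric data row {line!r}", line=lineno) from None
    for key in _REQUIRED_KEYS:
        if key not in metadata:
            raise ParseError(f"missing required metadata key #{key}=")
    if not saw_header:
        raise ParseError("missing 'position_mm,value' column header")
    if len(positions) == 0:
        raise ParseError("scan file contains no data rows")
    diffs = np.diff(positions)
    if np.any(diffs == 0):
        raise ValidationError("duplicate positions in scan file")
    if np.any(diffs < 0):
        raise ValidationError("positions must be strictly increasing")
    return ScanCurve(tuple(positions), tuple(values), metadata)


def write_table_csv(frame: pd.DataFrame, path, provenance: dict | None = None) -> None:
    """Write a table with optional ``#key=value`` provenance comment lines."""
    buf = _io.StringIO()
    for key, val in (provenance or {}).items():
        buf.write(f"#{key}={val}\n")
    frame.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def read_table_csv(path, required_columns=()) -> pd.DataFrame:
    """Read a table written by :func:`write_table_csv` (comments skipped)."""
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:  # pandas raises several parse error types
        raise ParseError(f"cannot parse table {path}: {exc}") from exc
    missing = [c for c in required_columns if c not in frame.columns]
    if missing:
        raise ParseError(f"table {path} missing columns {missing}")
    return frame
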