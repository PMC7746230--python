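"""ASCII force-curve files and CSV metric tables.

Curve files are plain text: an optional ``#``-prefixed header block of
key=value metadata lines followed by numeric rows.  The column order,
delimiter and units are declared by a Dialect — instrument exports
vary, so nothing about the layout is guessed.  Internally everything
is SI (seconds, metres, volts); unit conversion happens here, once.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import ForceCurveCycle, PullMetrics, ValidationError

log = logging.getLogger("afmbone")

_LENGTH_UNITS = {"m": 1.0, "mm": 1e-3, "um": 1e-6, "nm": 1e-9}
_TIME_UNITS = {"s": 1.0, "ms": 1e-3}
_DEFLECTION_UNITS = {"V": 1.0, "mV": 1e-3}

KNOWN_COLUMNS = ("time", "z_position", "deflection", "segment")


class ParseError(ValueError):
    """Malformed curve file; message names the offending line."""


@dataclass
class Dialect:
    """Declared layout of an ASCII curve file.

    columns: names in file order, from {"time", "z_position",
    "deflection", "segment"} (segment optional).
    delimiter: None for whitespace, or an explicit character such as ",".
    units: per-column units, converted to SI on read.
    """

    columns: Sequence[str] = ("time", "z_position", "deflection")
    delimiter: Optional[str] = None
    units: dict = field(default_factory=lambda: {
        "time": "s", "z_position": "m", "deflection": "V"})

    def __post_init__(self):
        unknown = set(self.columns) - set(KNOWN_COLUMNS)
        if unknown:
            raise ValidationError(f"undeclared columns in dialect: {sorted(unknown)}")
        for col in ("time", "z_position", "deflection"):
            if col not in self.columns:
                raise ValidationError(f"dialect must declare a {col!r} column")
        if self.delimiter is not None and self.delimiter.strip() == "":
            raise ValidationError("delimiter must be None (whitespace) or a character")
        try:
            self.scale = {
                "time": _TIME_UNITS[self.units.get("time", "s")],
                "z_position": _LENGTH_UNITS[self.units.get("z_position", "m")],
                "deflection": _DEFLECTION_UNITS[self.units.get("deflection", "V")],
            }
        except KeyError as exc:
            raise ValidationError(f"unknown unit {exc} in dialect") from exc


def _parse_header_value(raw: str):
    try:
        return float(raw)
    except ValueError:
        return raw


def read_ascii_curve(path, dialect: Optional[Dialect] = None) -> ForceCurveCycle:
    """Parse one ASCII curve file into a ForceCurveCycle.

    Header lines ``# key=value`` populate metadata; rows must match the
    dialect's column count.  Errors name the offending line number.
    """
    dialect = dialect if dialect is not None else Dialect()
    metadata = {}
    cols = {name: [] for name in dialect.columns}
    ncol = len(dialect.columns)
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    metadata[key.strip()] = _parse_header_value(val.strip())
                continue
            parts = line.split(dialect.delimiter)
            parts = [p for p in parts if p != ""]
            if len(parts) != ncol:
                raise ParseError(
                    f"{path}: line {lineno}: expected {ncol} columns, "
                    f"found {len(parts)}")
            for name, value in zip(dialect.columns, parts):
                if name == "segment":
                    cols[name].append(value)
                else:
                    try:
                        cols[name].append(float(value))
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: cannot parse {value!r} "
                            f"as a number in column {name!r}") from None
    if len(cols["time"]) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    time = np.array(cols["time"]) * dialect.scale["time"]
    dt = np.diff(time)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2  # second row of the offending pair
        raise ValidationError(
            f"{path}: time not strictly increasing at data row {bad}")
    seg = None
    if "segment" in dialect.columns:
        seg = np.array([s if s in ("approach", "dwell", "retract") else "unknown"
                        for s in cols["segment"]], dtype=object)
    return ForceCurveCycle(
        time=time,
        z_position=np.array(cols["z_position"]) * dialect.scale["z_position"],
        deflection_raw=np.array(cols["deflection"]) * dialect.scale["deflection"],
        segment_label=seg, metadata=metadata)


def write_ascii_curve(cycle: ForceCurveCycle, path,
                      dialect: Optional[Dialect] = None) -> None:
    """Emit a cycle in the ASCII format read_ascii_curve accepts (SI units)."""
    dialect = dialect if dialect is not None else Dialect()
    sep = dialect.delimiter if dialect.delimiter is not None else " "
    with open(path, "w") as fh:
        for key in sorted(cycle.metadata):
            fh.write(f"# {key}={cycle.metadata[key]}\n")
        arrays = {"time": cycle.time, "z_position": cycle.z_position,
                  "deflection": cycle.deflection_raw}
        for i in range(len(cycle)):
            fields = []
            for name in dialect.columns:
                if name == "segment":
                    lbl = (cycle.segment_label[i]
                           if cycle.segment_label is not None else "unknown")
                    fields.append(str(lbl))
                else:
                    fields.append(f"{arrays[name][i]:.12e}")
            fh.write(sep.join(fields) + "\n")


METRICS_COLUMNS = ["source_id", "condition", "max_force_N", "pulling_length_m",
                   "energy_J", "n_points", "rejected", "rejection_reason"]


def metrics_to_frame(metrics: Sequence[PullMetrics]) -> pd.DataFrame:
    rows = [dict(source_id=m.source_id, condition=m.condition,
                 max_force_N=m.max_force, pulling_length_m=m.pulling_length,
                 energy_J=m.energy, n_points=m.n_points, rejected=m.rejected,
                 rejection_reason=m.rejection_reason) for m in metrics]
    return pd.DataFrame(rows, columns=METRICS_COLUMNS)


def write_metrics_table(metrics: Union[Sequence[PullMetrics], pd.DataFrame],
                        path) -> int:
    """Write a delimited metrics table; returns the row count.

    Column order is stable and units are encoded in the header names,
    so a write -> read round trip is bit-identical at the serialized
    precision.
    """
    if isinstance(metrics, pd.DataFrame):
        frame = metrics
    else:
        frame = metrics_to_frame(list(metrics))
    if len(frame) == 0:
        raise ValidationError("refusing to write an empty metrics table")
    frame.to_csv(path, index=False, float_format="%.12e")
    return len(frame)


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False,
                       na_values=[], dtype={"rejection_reason": str})
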