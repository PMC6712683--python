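"""Delimited-text I/O, schemas and report writing.

Canonical interchange is comma-separated UTF-8 text with '.' decimals and a
header row whose column names carry the unit suffix (``temp_C``,
``q_pa_Lmin``, ...). Time is stored in hours post-inoculation; Celsius is
converted to Kelvin at the reader boundary. Unknown columns are preserved,
never silently dropped.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, SchemaError
from .our import OnlineRecord
from .solubility import celsius_to_kelvin


@dataclass(frozen=True)
class TraceSchema:
    """Column schema of a delimited on-line trace."""

    required: tuple = (
        "time_h", "temp_C", "do_pct", "pid_pct",
        "q_pa_Lmin", "q_co2_Lmin", "volume_L",
    )
    optional: tuple = (
        "offgas_o2_pct", "offgas_temp_C", "permittivity_pFcm",
        "conductivity_mScm",
    )


ONLINE_SCHEMA = TraceSchema()

OFFLINE_REQUIRED = ("time_h", "pcv_pct", "viability_pct")
CHARACTERIZATION_REQUIRED = ("liquid", "temp_C", "pid_pct", "kla_h")


def _read_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header row") from exc
    return df


def read_trace(path, schema: TraceSchema = ONLINE_SCHEMA) -> pd.DataFrame:
    """Read an on-line trace; validates the schema and monotone time.

    Returns the frame as stored (units in column names); use
    :func:`trace_records` for unit-converted :class:`OnlineRecord` objects.
    """
    df = _read_csv(path)
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    t = df["time_h"].to_numpy(dtype=float)
    if t.size and np.any(np.diff(t) < 0):
        raise DataError(f"{path}: time_h is not non-decreasing")
    return df


def trace_records(df: pd.DataFrame) -> list[OnlineRecord]:
    """Convert a validated on-line trace frame to OnlineRecord objects
    (Celsius -> Kelvin)."""
    def opt(row, col, convert=None):
        if col not in df.columns:
            return None
        val = row[col]
        if pd.isna(val):
            return None
        return convert(val) if convert else float(val)

    records = []
    for _, row in df.iterrows():
        records.append(
            OnlineRecord(
                t=float(row["time_h"]),
                temp_k=celsius_to_kelvin(float(row["temp_C"])),
                do_pct=float(row["do_pct"]),
                pid_pct=float(row["pid_pct"]),
                q_pa=float(row["q_pa_Lmin"]),
                q_co2=float(row["q_co2_Lmin"]),
                volume=float(row["volume_L"]),
                offgas_o2_pct=opt(row, "offgas_o2_pct"),
                offgas_temp_k=opt(row, "offgas_temp_C", celsius_to_kelvin),
                permittivity=opt(row, "permittivity_pFcm"),
                conductivity=opt(row, "conductivity_mScm"),
            )
        )
    return records


def write_trace(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_offline(path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in OFFLINE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_characterization(path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in CHARACTERIZATION_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def load_config(path) -> dict:
    """Load the structured YAML configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def format_report(blocks: dict) -> str:
    """Render model coefficients / metrics as a deterministic text report.

    ``blocks`` maps a block title to a mapping of field -> value; fields are
    emitted in insertion order so identical inputs give byte-identical
    bodies (human-readable and machine-parsable as ``key: value``).
    """
    buf = _io.StringIO()
    for title, fields in blocks.items():
        buf.write(f"[{title}]\n")
        for key, value in fields.items():
            if isinstance(value, float):
                buf.write(f"{key}: {value:.10g}\n")
            else:
                buf.write(f"{key}: {value}\n")
        buf.write("\n")
    return buf.getvalue()


def write_report(blocks: dict, path) -> str:
    """Write :func:`format_report` output to ``path``; returns the body."""
    body = format_report(blocks)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(body, encoding="utf-8")
    return body
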