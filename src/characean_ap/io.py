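"""Serialization: trace CSV, ensemble CSV and parameter-set YAML.

Trace files are plain UTF-8 CSV (comma separator, dot decimal) with header
``time_s,pd_mV`` and optional ``#``-prefixed metadata lines; values round-trip
at full double precision.  Parameter-set files are YAML mirroring
ParameterSet, optionally inheriting from a bundled registry column via a
``base:`` block with field-level overrides — the same resolution rule the
printed tables use for blank cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .errors import FormatError, SchemaError
from .parameters import ParameterSet
from .tables import load_parameter_set
from .traces import EnsembleTrace, Trace

__all__ = ["read_trace", "write_trace", "read_ensemble", "write_ensemble",
           "read_parameter_set", "write_parameter_set"]

_TRACE_HEADER = "time_s,pd_mV"
_ENSEMBLE_HEADER = "time_s,mean_mV,sd_mV,n"


def _parse_float(token: str, path, lineno: int) -> float:
    try:
        return float(token)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: cannot parse {token!r} as a number "
            "(decimal comma? locale output is not accepted)") from None


def write_trace(tr: Trace, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for key, value in tr.meta.items():
            fh.write(f"# {key}: {json.dumps(value, default=str)}\n")
        fh.write(_TRACE_HEADER + "\n")
        for t, v in zip(tr.t, tr.v):
            fh.write(f"{t:.17g},{v:.17g}\n")


def read_trace(path) -> Trace:
    path = Path(path)
    meta: dict = {}
    t_vals: list[float] = []
    v_vals: list[float] = []
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    key, _, val = body.partition(":")
                    try:
                        meta[key.strip()] = json.loads(val.strip())
                    except json.JSONDecodeError:
                        meta[key.strip()] = val.strip()
                continue
            if not header_seen:
                if line != _TRACE_HEADER:
                    raise FormatError(
                        f"{path}:{lineno}: expected header {_TRACE_HEADER!r}, "
                        f"got {line!r}")
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 comma-separated fields, "
                    f"got {len(fields)} ({line!r})")
            t_vals.append(_parse_float(fields[0], path, lineno))
            v_vals.append(_parse_float(fields[1], path, lineno))
    if not header_seen or not t_vals:
        raise FormatError(f"{path}: no trace data found")
    t = np.array(t_vals)
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if len(bad):
        i = int(bad[0])
        raise FormatError(
            f"{path}: time must be strictly increasing and uniform; "
            f"first bad interval is #{i} ({t[i]!r} -> {t[i + 1]!r})")
    step = dt[0]
    off = np.flatnonzero(np.abs(dt - step) > 1e-9)
    if len(off):
        i = int(off[0])
        raise FormatError(
            f"{path}: non-uniform sampling; first bad interval is #{i} "
            f"({dt[i]!r} s vs step {step!r} s)")
    return Trace(t=t, v=np.array(v_vals), meta=meta)


def write_ensemble(e: EnsembleTrace, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(_ENSEMBLE_HEADER + "\n")
        for t, m, s in zip(e.t, e.mean, e.sd):
            fh.write(f"{t:.17g},{m:.17g},{s:.17g},{e.n}\n")


def read_ensemble(path) -> EnsembleTrace:
    path = Path(path)
    rows = []
    n = None
    header_seen = False
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if line != _ENSEMBLE_HEADER:
                    raise FormatError(
                        f"{path}:{lineno}: expected header "
                        f"{_ENSEMBLE_HEADER!r}, got {line!r}")
                header_seen = True
                continue
            fields = line.split(",")
            if len(fields) != 4:
                raise FormatError(
                    f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            rows.append([_parse_float(f, path, lineno) for f in fields[:3]])
            n = int(fields[3])
    if not rows:
        raise FormatError(f"{path}: no ensemble data found")
    arr = np.array(rows)
    return EnsembleTrace(t=arr[:, 0], mean=arr[:, 1], sd=arr[:, 2], n=n)


def write_parameter_set(ps: ParameterSet, path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(ps.to_dict(), fh, sort_keys=False)


def _deep_update(base: dict, overrides: dict, where: str = "") -> dict:
    out = dict(base)
    for key, val in overrides.items():
        if key not in base:
            raise SchemaError(f"unknown field {where + key!r}")
        if isinstance(val, dict) and isinstance(base[key], dict):
            out[key] = _deep_update(base[key], val, where + key + ".")
        else:
            out[key] = val
    return out


def read_parameter_set(path) -> ParameterSet:
    """Read a parameter-set YAML file.

    A ``base: {table: N, column: LABEL}`` block resolves the named registry
    column first; every other field then overrides it (the explicit-inherit
    analogue of the printed tables' blank convention).  Without ``base`` the
    file must be complete.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"{path}: expected a mapping at top level")
    base_ref = doc.pop("base", None)
    if base_ref is not None:
        if set(base_ref) != {"table", "column"}:
            raise SchemaError("base block must be {table, column}")
        base_ps = load_parameter_set(base_ref["table"], base_ref["column"])
        merged = _deep_update(base_ps.to_dict(), doc)
        return ParameterSet.from_dict(merged)
    return ParameterSet.from_dict(doc)
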