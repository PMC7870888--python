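"""Trace file I/O: tidy CSV (primary) and Axon Text File export.

CSV layout is long-form with one row per sample:
``sweep, step_mV, holding_mV, rs_mohm, cm_pf, t_ms, vcmd_mV, vm_mV, i_nA``.
Column names carry units, and potentials are command-side unless labelled
``vm``: the V_cmd / V_m distinction is the whole point of the simulator
and must stay unambiguous on disk.  Values are written with 10 significant
digits, so a round trip is lossless to better than 1e-9 relative.

The ATF export writes a standard Axon Text File (one time column plus one
current signal per sweep) readable by common electrophysiology analysis
software; it carries the currents only, not the Vm traces.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError, ParseError
from .simulate import SweepTrace

__all__ = ["traces_to_frame", "write_traces", "read_traces"]

_CSV_COLUMNS = ["sweep", "step_mV", "holding_mV", "rs_mohm", "cm_pf",
                "t_ms", "vcmd_mV", "vm_mV", "i_nA"]
_FLOAT_FMT = "%.10g"


def traces_to_frame(traces: list[SweepTrace]) -> pd.DataFrame:
    """Stack sweeps into one tidy long-form DataFrame."""
    frames = []
    for k, tr in enumerate(traces):
        frames.append(pd.DataFrame({
            "sweep": k,
            "step_mV": tr.step_mV,
            "holding_mV": tr.holding_mV,
            "rs_mohm": tr.rs_mohm,
            "cm_pf": tr.cm_pf,
            "t_ms": tr.t_ms,
            "vcmd_mV": tr.vcmd_mV,
            "vm_mV": tr.vm_mV,
            "i_nA": tr.i_nA,
        }))
    if not frames:
        return pd.DataFrame(columns=_CSV_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def write_traces(traces: list[SweepTrace], path, format: str = "csv") -> None:
    """Write sweeps to ``path`` as tidy CSV or ATF."""
    path = Path(path)
    if format == "csv":
        traces_to_frame(traces).to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif format == "atf":
        _write_atf(traces, path)
    else:
        raise InvalidInputError(f"unknown trace format {format!r}")


def read_traces(path, format: str = "csv") -> list[SweepTrace]:
    """Read sweeps back from a CSV or ATF file."""
    path = Path(path)
    if format == "csv":
        return _read_csv(path)
    if format == "atf":
        return _read_atf(path)
    raise InvalidInputError(f"unknown trace format {format!r}")


def _read_csv(path: Path) -> list[SweepTrace]:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        line = getattr(exc, "lineno", None)
        raise ParseError(f"malformed CSV trace file {path}: {exc}", line=line) from exc
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}", line=1)
    traces = []
    for _, sub in df.groupby("sweep", sort=True):
        traces.append(SweepTrace(
            t_ms=sub["t_ms"].to_numpy(float),
            vcmd_mV=sub["vcmd_mV"].to_numpy(float),
            vm_mV=sub["vm_mV"].to_numpy(float),
            i_nA=sub["i_nA"].to_numpy(float),
            step_mV=float(sub["step_mV"].iloc[0]),
            holding_mV=float(sub["holding_mV"].iloc[0]),
            rs_mohm=float(sub["rs_mohm"].iloc[0]),
            cm_pf=float(sub["cm_pf"].iloc[0]),
        ))
    return traces


# --------------------------------------------------------------------------
# Axon Text File
# --------------------------------------------------------------------------

def _write_atf(traces: list[SweepTrace], path: Path) -> None:
    if traces:
        t = traces[0].t_ms
        for tr in traces[1:]:
            if len(tr.t_ms) != len(t):
                raise InvalidInputError("ATF export requires equal-length sweeps")
    headers = ['"Time (ms)"'] + [
        f'"I step {tr.step_mV:g} mV (nA)"' for tr in traces
    ]
    records = [
        f'"SweepCount={len(traces)}"',
        '"SignalsExported=i_nA"',
    ] + ([f'"HoldingPotential_mV={traces[0].holding_mV:g}"',
          f'"SeriesResistance_MOhm={traces[0].rs_mohm:g}"'] if traces else [])
    buf = _stdio.StringIO()
    buf.write("ATF\t1.0\n")
    buf.write(f"{len(records)}\t{len(headers)}\n")
    for rec in records:
        buf.write(rec + "\n")
    buf.write("\t".join(headers) + "\n")
    if traces:
        data = np.column_stack([traces[0].t_ms] + [tr.i_nA for tr in traces])
        for row in data:
            buf.write("\t".join(_FLOAT_FMT % x for x in row) + "\n")
    path.write_text(buf.getvalue())


def _read_atf(path: Path) -> list[SweepTrace]:
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("ATF"):
        raise ParseError(f"{path}: not an ATF file", line=1)
    try:
        n_records, n_cols = (int(x) for x in lines[1].split("\t"))
    except (IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed ATF dimension line", line=2) from exc
    meta = {}
    for rec in lines[2: 2 + n_records]:
        body = rec.strip().strip('"')
        if "=" in body:
            key, val = body.split("=", 1)
            meta[key] = val
    header_line = 2 + n_records
    headers = lines[header_line].split("\t")
    if len(headers) != n_cols:
        raise ParseError(f"{path}: expected {n_cols} columns, found {len(headers)}",
                         line=header_line + 1)
    steps = []
    for h in headers[1:]:
        try:
            steps.append(float(h.strip('"').split()[2]))
        except (IndexError, ValueError):
            steps.append(float("nan"))
    rows = []
    for ln, line in enumerate(lines[header_line + 1:], start=header_line + 2):
        if not line.strip():
            continue
        vals = line.split("\t")
        if len(vals) != n_cols:
            raise ParseError(f"{path}: row has {len(vals)} fields, expected {n_cols}",
                             line=ln)
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise ParseError(f"{path}: non-numeric value", line=ln) from exc
    data = np.asarray(rows)
    holding = float(meta.get("HoldingPotential_mV", "nan"))
    rs = float(meta.get("SeriesResistance_MOhm", "0"))
    traces = []
    if data.size == 0:
        return traces
    for k, step in enumerate(steps):
        vcmd = np.full(len(data), step)
        traces.append(SweepTrace(
            t_ms=data[:, 0], vcmd_mV=vcmd, vm_mV=vcmd.copy(),
            i_nA=data[:, k + 1], step_mV=step, holding_mV=holding,
            rs_mohm=rs,
        ))
    return traces
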