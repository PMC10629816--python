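"""File formats: trace/feature/kinetics CSV tables and result JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Trace

__all__ = [
    "TRACE_COLUMNS",
    "TraceFormatError",
    "write_traces",
    "read_traces",
    "export_results",
    "import_results",
]

TRACE_COLUMNS = ["nucleus_id", "genotype", "dv_position", "t_s", "intensity_au"]


class TraceFormatError(ValueError):
    """A trace table violates the schema; the message names the file line."""


def write_traces(traces: list[Trace], path: str | Path, truth_path: str | Path | None = None) -> None:
    """Write traces as a long-format CSV (and optionally a truth sidecar JSON)."""
    rows = []
    for tr in traces:
        for t, i in zip(tr.t, tr.intensity):
            rows.append((tr.nucleus_id, tr.genotype, tr.dv_position, t, i))
    pd.DataFrame(rows, columns=TRACE_COLUMNS).to_csv(path, index=False)
    if truth_path is not None:
        truth = {tr.nucleus_id: tr.truth for tr in traces if tr.truth is not None}
        Path(truth_path).write_text(json.dumps(truth))


def read_traces(path: str | Path, truth_path: str | Path | None = None) -> list[Trace]:
    """Read a trace CSV back into :class:`Trace` objects.

    Rows are sorted by time within each nucleus, so shuffled files load
    identically.  Schema violations raise :class:`TraceFormatError` naming
    the offending file line (header is line 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: missing column(s) {missing}")
    bad = df[TRACE_COLUMNS].isna().any(axis=1)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise TraceFormatError(f"{path}: malformed row at line {line}")
    truth = {}
    if truth_path is not None and Path(truth_path).exists():
        truth = json.loads(Path(truth_path).read_text())
    traces = []
    for nid, sub in df.groupby("nucleus_id", sort=True):
        sub = sub.sort_values("t_s")
        t = sub["t_s"].to_numpy(dtype=float)
        if t.size >= 2:
            dt = np.diff(t)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9):
                raise TraceFormatError(f"{path}: nonuniform time grid for nucleus {nid!r}")
        tr = Trace(
            nucleus_id=str(nid),
            dv_position=float(sub["dv_position"].iloc[0]),
            genotype=str(sub["genotype"].iloc[0]),
            t=t,
            intensity=sub["intensity_au"].to_numpy(dtype=float),
            truth=truth.get(str(nid)),
        )
        traces.append(tr)
    return traces


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    return obj


def export_results(
    path: str | Path,
    omega: np.ndarray | None = None,
    occupancy: pd.DataFrame | None = None,
    kinetics: pd.DataFrame | None = None,
    extra: dict | None = None,
) -> dict:
    """Write fitted cooperativities, occupancy table and kinetics to JSON.

    The 11 cooperativities are emitted as named entries ``omega_1`` ..
    ``omega_11``; occupancy rows keep their ``omega_<i>`` state labels.
    Returns the payload that was written.
    """
    payload: dict = {}
    if omega is not None:
        om = np.asarray(omega, dtype=float)
        payload["cooperativities"] = {f"omega_{i}": float(v) for i, v in enumerate(om, 1)}
    if occupancy is not None:
        payload["occupancy_table"] = _jsonable(occupancy)
    if kinetics is not None:
        payload["kinetics_summary"] = _jsonable(kinetics)
    if extra:
        payload.update(_jsonable(extra))
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return payload


def import_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
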