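"""Plain-text trace serialization.

A trace file is a block of ``# key = value`` metadata lines followed by
tab-separated columns ``time  voltage  current`` and optionally
``g_syn``.  Units are fixed (ms, mV, pA, nS).  Unknown metadata keys are
preserved verbatim on a round trip.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParameterError
from .model import Trace

_MAGIC = "tspn-trace v1"
_UNITS = "ms,mV,pA,nS"


def write_trace(trace: Trace, path) -> None:
    path = Path(path)
    lines = [f"# {_MAGIC}", f"# dt = {trace.dt!r}", f"# units = {_UNITS}"]
    for key, val in trace.meta.items():
        if key in ("dt", "final_state", "step_window"):
            continue
        lines.append(f"# {key} = {val}")
    cols = ["time", "voltage", "current"]
    data = [trace.t, trace.v, trace.i_inj]
    if trace.g_syn is not None:
        cols.append("g_syn")
        data.append(trace.g_syn)
    lines.append("\t".join(cols))
    body = np.column_stack(data)
    with path.open("w") as fh:
        fh.write("\n".join(lines) + "\n")
        np.savetxt(fh, body, fmt="%.9g", delimiter="\t")


def read_trace(path) -> Trace:
    path = Path(path)
    meta: dict = {}
    header_cols: list[str] | None = None
    rows: list[list[float]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body == _MAGIC:
                    continue
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            if header_cols is None:
                header_cols = parts
                if parts[:3] != ["time", "voltage", "current"]:
                    raise ParameterError(
                        f"line {lineno}: unexpected column header {parts!r}")
                continue
            if len(parts) != len(header_cols):
                raise ParameterError(
                    f"line {lineno}: expected {len(header_cols)} columns, "
                    f"found {len(parts)}")
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParameterError(f"line {lineno}: {exc}") from exc
    if header_cols is None or not rows:
        raise ParameterError("no data rows found")
    arr = np.asarray(rows)
    try:
        dt = float(meta.pop("dt"))
    except KeyError as exc:
        raise ParameterError("missing dt metadata") from exc
    meta.pop("units", None)
    g_syn = arr[:, 3] if len(header_cols) > 3 else None
    return Trace(dt=dt, v=arr[:, 1], i_inj=arr[:, 2], g_syn=g_syn, meta=meta)
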