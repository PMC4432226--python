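"""Plain-text I/O: traces as commented-header matrix files, tables as
CSV, ground truth and summaries as JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Trace

__all__ = ["write_trace", "read_trace", "write_json", "read_json"]


def write_trace(path: str | Path, trace: Trace) -> None:
    """Header lines ('# key: value') followed by time/value columns."""
    path = Path(path)
    header = f"# kind: {trace.kind}\n# dt_ms: {trace.dt!r}\n# t0_ms: {trace.t0!r}\n# columns: time_ms value\n"
    data = np.column_stack([trace.times, trace.samples])
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.9g")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    data = np.loadtxt(path, comments="#")
    if data.ndim == 1:
        data = data.reshape(1, -1)
    return Trace(
        dt=float(meta["dt_ms"]),
        samples=data[:, 1],
        kind=meta.get("kind", "voltage"),
        t0=float(meta.get("t0_ms", data[0, 0] if len(data) else 0.0)),
    )


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyEncoder))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
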