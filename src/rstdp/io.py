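"""Serialization: canonical JSON records, CSV traces, HDF5 weight snapshots.

Outcome records are written as canonical JSON (sorted keys, fixed float
format at 12 significant digits) so that repeated runs of the same
configuration produce byte-identical files and diffs stay readable.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

__all__ = ["canonical_json", "write_outcome", "read_outcome",
           "write_trace_csv", "write_weight_snapshots", "read_weight_snapshots"]

_FLOAT_DIGITS = 12


def _canonize(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _canonize(v) for k, v in sorted(obj.items())}
    if isinstance(obj, (list, tuple)):
        return [_canonize(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        if math.isnan(x):
            return None
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        if x == int(x) and abs(x) < 1e15:
            return x
        return float(f"{x:.{_FLOAT_DIGITS}g}")
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _canonize(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def canonical_json(obj: Any) -> str:
    """Deterministic JSON text for a (possibly numpy-laden) object tree."""
    return json.dumps(_canonize(obj), sort_keys=True, indent=1,
                      ensure_ascii=False) + "\n"


def write_outcome(record, path: str | Path, extra: dict | None = None) -> None:
    """Write an outcome record (plus optional config/seed info) as JSON."""
    payload = record.to_dict() if hasattr(record, "to_dict") else dict(record)
    if extra:
        payload.update(extra)
    Path(path).write_text(canonical_json(payload))


def read_outcome(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_trace_csv(trace: pd.DataFrame, path: str | Path) -> None:
    """Diagnostics trace with a stable header and float format."""
    trace.to_csv(path, index=False, float_format=f"%.{_FLOAT_DIGITS}g")


def write_weight_snapshots(
    snapshots: dict[int, np.ndarray], path: str | Path
) -> None:
    """Store weight matrices under ``/W/<N>`` in an HDF5 file."""
    import h5py

    with h5py.File(path, "w") as handle:
        group = handle.create_group("W")
        for N, W in sorted(snapshots.items()):
            group.create_dataset(str(int(N)), data=np.asarray(W, dtype=float))


def read_weight_snapshots(path: str | Path) -> dict[int, np.ndarray]:
    import h5py

    out: dict[int, np.ndarray] = {}
    with h5py.File(path, "r") as handle:
        for name, dataset in handle["W"].items():
            out[int(name)] = np.asarray(dataset)
    return out
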