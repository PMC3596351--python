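"""Plain-text readers/writers used across the pipeline.

Series travel as two-column delimited text (time in seconds, value); analysis
summaries travel as flat JSON records stamped with the package version and a
hash of the configuration that produced them.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .preprocess import ActivitySeries

__all__ = [
    "read_series",
    "write_series",
    "write_record",
    "read_record",
    "config_hash",
]


def read_series(path: str | Path, normalized: bool = False) -> ActivitySeries:
    """Read a two-column (time_s, value) text file into an ActivitySeries.

    A single header line is tolerated.  The time column must be uniformly
    spaced; its spacing becomes ``dt``.
    """
    path = Path(path)
    try:
        data = np.loadtxt(path, ndmin=2)
    except ValueError:
        data = np.loadtxt(path, skiprows=1, ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time_s, value)")
    t, v = data[:, 0], data[:, 1]
    if len(t) < 2:
        raise ValueError(f"{path}: need at least 2 samples")
    steps = np.diff(t)
    dt = float(np.median(steps))
    if dt <= 0 or not np.allclose(steps, dt, rtol=1e-6, atol=1e-9):
        raise ValueError(f"{path}: time column is not uniformly spaced")
    return ActivitySeries(dt=dt, values=v, normalized=normalized, t0=float(t[0]))


def write_series(path: str | Path, series: ActivitySeries, header: bool = True) -> None:
    """Write an ActivitySeries as full-precision two-column text."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header:
            fh.write("time_s\tvalue\n")
        for t, v in zip(series.times, series.values):
            fh.write(f"{t:.10g}\t{v:.17g}\n")


def config_hash(config: Mapping[str, Any]) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_record(
    path: str | Path, record: Mapping[str, Any], config: Mapping[str, Any] | None = None
) -> None:
    """Write a flat JSON record, stamped with version and config hash."""
    from . import __version__

    out = dict(record)
    out["_version"] = __version__
    if config is not None:
        out["_config_hash"] = config_hash(config)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=2, default=_jsonify)
        fh.write("\n")


def read_record(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return json.load(fh)


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
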