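"""Trajectory CSV and manifest I/O.

Trajectories travel as delimited text with the header ``t_s,x_cm,y_cm``
(time in seconds, positions in cm); every run directory carries a JSON
manifest echoing the exact configuration and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import Trajectory

__all__ = ["read_trajectory", "write_trajectory", "write_manifest",
           "read_manifest", "TrajectoryFormatError"]

HEADER = ("t_s", "x_cm", "y_cm")


class TrajectoryFormatError(ValueError):
    """Malformed trajectory file (missing columns, bad time base, ...)."""


def read_trajectory(path: str | Path, rate: float | None = None) -> Trajectory:
    """Read and validate a trajectory CSV.

    The sampling rate is taken from ``rate`` if given, otherwise
    inferred from the median time step.  Non-monotone or duplicated
    timestamps are reported with their line number (header = line 1).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in HEADER if c not in df.columns]
    if missing:
        raise TrajectoryFormatError(
            f"{path}: missing column(s) {missing}; expected header "
            f"{','.join(HEADER)}"
        )
    bad = df[list(HEADER)].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise TrajectoryFormatError(f"{path}: malformed row at line {line}")
    t = df["t_s"].to_numpy(float)
    dt = np.diff(t)
    nonpos = np.flatnonzero(dt <= 0)
    if len(nonpos) > 0:
        line = int(nonpos[0]) + 3  # second row of the offending pair
        kind = "duplicated" if dt[nonpos[0]] == 0 else "non-monotone"
        raise TrajectoryFormatError(f"{path}: {kind} timestamp at line {line}")
    if rate is None:
        rate = 1.0 / float(np.median(dt))
    try:
        return Trajectory(t=t, x=df["x_cm"].to_numpy(float),
                          y=df["y_cm"].to_numpy(float), rate=rate)
    except ValueError as exc:
        raise TrajectoryFormatError(f"{path}: {exc}") from exc


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t_s": traj.t, "x_cm": traj.x, "y_cm": traj.y}).to_csv(
        path, index=False, float_format="%.10g"
    )


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(data: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True))


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
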