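"""Reading and writing pose logs and related tables.

Pose log format: CSV with the mandatory header ``t,qw,qx,qy,qz,tx,ty,tz``
(seconds, unit quaternion, millimetres), one sample per row, strictly
non-decreasing timestamps. Values are written with 9 significant digits so a
write/read round trip is lossless at that precision. Malformed rows are
rejected with line-numbered diagnostics.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import RigidPose

__all__ = ["POSE_COLUMNS", "read_pose_log", "write_pose_log"]

POSE_COLUMNS = ["t", "qw", "qx", "qy", "qz", "tx", "ty", "tz"]
_QUAT_TOL = 1e-6


def read_pose_log(path: str | Path) -> list[RigidPose]:
    """Read a pose log CSV into a list of :class:`RigidPose`.

    A header-only file yields an empty stream. Non-monotone timestamps and
    quaternions whose norm deviates from 1 beyond 1e-6 are rejected with the
    offending line number (1-based, header = line 1).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file (expected header {','.join(POSE_COLUMNS)})")
    if list(df.columns) != POSE_COLUMNS:
        raise ValueError(
            f"{path}: bad header {list(df.columns)}; expected {POSE_COLUMNS}"
        )
    for col in POSE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}:{row + 2}: missing or non-numeric value {df[col].iloc[row]!r} in column {col!r}"
            )
        df[col] = coerced
    t = df["t"].to_numpy(dtype=float)
    if np.any(np.diff(t) < 0):
        row = int(np.argmax(np.diff(t) < 0)) + 1
        raise ValueError(f"{path}:{row + 2}: non-monotone timestamp {t[row]} after {t[row - 1]}")
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(q, axis=1)
    bad = np.abs(norms - 1.0) > _QUAT_TOL
    if np.any(bad):
        row = int(np.argmax(bad))
        raise ValueError(
            f"{path}:{row + 2}: quaternion norm {norms[row]:.9f} deviates from 1 beyond {_QUAT_TOL}"
        )
    p = df[["tx", "ty", "tz"]].to_numpy(dtype=float)
    return [RigidPose(t=float(t[i]), q=q[i], p=p[i]) for i in range(len(df))]


def write_pose_log(stream: Sequence[RigidPose], path: str | Path) -> None:
    """Write a pose stream as CSV with 9 significant digits."""
    rows = [[p.t, *p.q, *p.p] for p in stream]
    df = pd.DataFrame(rows, columns=POSE_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g", lineterminator="\n")
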