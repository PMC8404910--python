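"""Performance metrics: task time, Euclidean path, outlier filtering, summaries.

The Euclidean path is the cumulative travel distance of a tracked point on
the tool — the sum of distances between successive recorded positions — and
measures how directly the operator steered toward the final pose. The
outlier rule excludes values outside mean ± 2·std in a single pass; the
sample standard deviation (n−1 denominator) is used throughout.
"""

from __future__ import annotations

from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "METRIC_COLUMNS",
    "euclidean_path",
    "task_time",
    "filter_outliers",
    "summarize_groups",
]

#: Canonical column set for a metric table (one row per trial).
METRIC_COLUMNS = [
    "participant",
    "condition",
    "trajectory_id",
    "task_time_s",
    "euclidean_path_mm",
    "success",
]


def euclidean_path(
    log: Sequence,
    tool=None,
    point: Literal["tool_origin", "tip"] = "tool_origin",
) -> float:
    """Total Euclidean path (mm) of a tracked point over a pose log.

    ``log`` may be a sequence of :class:`~tminav.geometry.RigidPose` (with
    ``tool`` selecting the tracked point: the tool origin by default, or the
    tip) or a plain (n, 3) array of positions. A single sample gives 0.
    """
    if len(log) == 0:
        raise ValueError("empty pose log")
    first = log[0]
    if hasattr(first, "q"):
        if point == "tip":
            if tool is None:
                raise ValueError("tip path requires a ToolGeometry")
            pts = np.array([p.rotation.apply(tool.tip_offset) + p.p for p in log])
        else:
            pts = np.array([p.p for p in log])
    else:
        pts = np.asarray(log, dtype=float).reshape(len(log), 3)
    if len(pts) < 2:
        return 0.0
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def task_time(result) -> float:
    """Task time (s) of a successful trial: ``t_success − t_start``.

    Unsuccessful trials have no task time; ``nan`` is returned as the
    explicit missing marker (never 0).
    """
    if not result.success:
        return float("nan")
    return float(result.t_success - result.t_start)


def filter_outliers(values: Sequence[float]) -> tuple[np.ndarray, np.ndarray]:
    """Single-pass mean ± 2·std exclusion.

    Computes the mean and sample std of the input once and keeps values in
    the closed interval [mean − 2·std, mean + 2·std]. A zero std (constant
    input) keeps everything. Returns ``(kept_values, keep_mask)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("outlier filtering needs at least 2 values")
    m, s = v.mean(), v.std(ddof=1)
    if s == 0.0:
        mask = np.ones(v.size, dtype=bool)
    else:
        mask = (v >= m - 2 * s) & (v <= m + 2 * s)
    return v[mask], mask


_GROUP_COLUMNS = {
    "condition": "condition",
    "experience": "experience",
    "region": "region",
}


def summarize_groups(
    table: pd.DataFrame,
    by: str = "condition",
    metrics: Sequence[str] = ("task_time_s", "euclidean_path_mm"),
) -> pd.DataFrame:
    """Per-group mean ± sample std of the given metric columns.

    ``by`` is one of ``condition``, ``experience`` or ``region`` (the study's
    grouping axes). Returns a DataFrame indexed by group with a
    (metric, {mean, std, n}) column MultiIndex; groups of size one report
    std 0 by convention.
    """
    if by not in _GROUP_COLUMNS:
        raise ValueError(f"unknown grouping key {by!r}; expected one of {sorted(_GROUP_COLUMNS)}")
    col = _GROUP_COLUMNS[by]
    if col not in table.columns:
        raise ValueError(f"table has no {col!r} column")
    metrics = [m for m in metrics if m in table.columns]
    if not metrics:
        raise ValueError("no requested metric columns present in the table")
    g = table.groupby(col, sort=True)[metrics]
    out = g.agg(["mean", "std", "count"]).rename(columns={"count": "n"})
    for m in metrics:
        out[(m, "std")] = out[(m, "std")].fillna(0.0)
    return out
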