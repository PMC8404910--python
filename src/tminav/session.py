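"""Trial execution: alignment-success detection and experiment protocols.

A trial is successful when the instrument stays continuously within the
angular tolerance for a full hold duration (2 s by default). The task time
runs from the first sample of the stream (the moment the visualization
appears) to the success event and therefore includes the hold; subtracting
``hold_duration`` recovers the alternative reading.

Protocols reproduce the study designs: per participant, a seeded random
permutation of the visualization conditions (block randomization), with
trajectory assignment per experiment — the spine study aligns two randomized
trajectories per side of the spine per visualization, the abstract
single-entry study repeats random trajectories a fixed number of times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .geometry import RigidPose, ToolGeometry, Trajectory, apply_tool_geometry, angular_deviation
from .metrics import euclidean_path

__all__ = [
    "CONDITIONS",
    "AlignmentDetector",
    "TrialSpec",
    "TrialResult",
    "ProtocolPlan",
    "run_trial",
    "make_protocol",
]

#: Closed set of visualization conditions used across the experiments.
CONDITIONS = (
    "circle_tmi",
    "grid_tmi",
    "circle_external",
    "grid_external",
    "traditional_external",
    "depth",
)


@dataclass
class AlignmentDetector:
    """Success detector implementing the continuous 2-s hold rule.

    Feed ``update(t, theta)`` with non-decreasing timestamps. A hold starts at
    the first in-tolerance sample; any out-of-tolerance sample before
    ``hold_duration`` has elapsed resets the search; success fires at the
    first timestamp ``t`` with ``t - hold_start >= hold_duration`` and is
    absorbing for the remainder of the trial. Timing uses timestamps, not
    sample counts, so dropped frames cannot shorten the hold.
    """

    tolerance_deg: float = 1.0
    hold_duration: float = 2.0
    state: Literal["searching", "holding", "success"] = "searching"
    hold_start: float | None = None
    success_time: float | None = None
    _last_t: float | None = None

    def update(self, t: float, theta: float) -> str:
        if self._last_t is not None and t < self._last_t:
            raise ValueError(f"timestamps must be non-decreasing (got {t} after {self._last_t})")
        self._last_t = t
        if self.state == "success":
            return self.state
        if theta <= self.tolerance_deg:
            if self.hold_start is None:
                self.hold_start = t
                self.state = "holding"
            if t - self.hold_start >= self.hold_duration:
                self.state = "success"
                self.success_time = t
        else:
            self.hold_start = None
            self.state = "searching"
        return self.state


@dataclass(frozen=True)
class TrialSpec:
    """One planned alignment trial: trajectory, condition, repetition index."""

    trajectory_id: str
    condition: str
    repetition: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")


@dataclass(frozen=True)
class TrialResult:
    """Outcome of one alignment trial.

    ``task_time`` and ``t_success`` are ``None`` for unsuccessful trials
    (the stream ended before the hold completed) — never zero.
    ``euclidean_path`` accumulates the tracked point's travel up to the
    success event (or the whole stream on failure).
    """

    spec: TrialSpec | None
    success: bool
    t_start: float
    t_success: float | None
    task_time: float | None
    euclidean_path: float
    events: tuple[tuple[float, str], ...]
    n_samples: int


def run_trial(
    stream: Sequence[RigidPose],
    traj: Trajectory,
    tool: ToolGeometry,
    tolerance_deg: float = 1.0,
    hold_duration: float = 2.0,
    reference: np.ndarray | None = None,
    path_point: Literal["tool_origin", "tip"] = "tool_origin",
    spec: TrialSpec | None = None,
) -> TrialResult:
    """Run the success detector over a pose stream and collect trial metrics."""
    if len(stream) == 0:
        raise ValueError("empty pose stream")
    det = AlignmentDetector(tolerance_deg=tolerance_deg, hold_duration=hold_duration)
    t_start = stream[0].t
    events: list[tuple[float, str]] = [(t_start, "trial_start")]
    prev_state = "searching"
    n_used = len(stream)
    for i, pose in enumerate(stream):
        _, axis = apply_tool_geometry(pose, tool)
        theta = angular_deviation(axis, traj.direction)
        state = det.update(pose.t, theta)
        if state != prev_state:
            if state == "holding":
                events.append((pose.t, "hold_start"))
            elif state == "searching":
                events.append((pose.t, "hold_reset"))
            elif state == "success":
                events.append((pose.t, "success"))
                n_used = i + 1
                break
            prev_state = state
    success = det.state == "success"
    path = euclidean_path(stream[:n_used], tool, point=path_point)
    return TrialResult(
        spec=spec,
        success=success,
        t_start=t_start,
        t_success=det.success_time,
        task_time=(det.success_time - t_start) if success else None,
        euclidean_path=path,
        events=tuple(events),
        n_samples=n_used,
    )


@dataclass(frozen=True)
class ProtocolPlan:
    """Block-randomized experiment plan: per-participant ordered trial lists."""

    participants: tuple[tuple[TrialSpec, ...], ...]
    seed: int

    def condition_order(self, participant: int) -> tuple[str, ...]:
        seen: list[str] = []
        for spec in self.participants[participant]:
            if spec.condition not in seen:
                seen.append(spec.condition)
        return tuple(seen)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "participants": [[asdict(s) for s in trials] for trials in self.participants],
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ProtocolPlan":
        payload = json.loads(Path(path).read_text())
        return cls(
            participants=tuple(
                tuple(TrialSpec(**s) for s in trials) for trials in payload["participants"]
            ),
            seed=payload["seed"],
        )


def _assign_spine_trajectories(
    rng: np.random.Generator, pool: dict[str, Sequence[str]], reps: int
) -> list[str]:
    # two randomized trajectories per side, repetitions split evenly over them
    ids: list[str] = []
    per_side = reps // 2
    for side in sorted(pool):
        chosen = list(rng.choice(np.asarray(pool[side], dtype=object), size=2, replace=False))
        for k in range(per_side):
            ids.append(chosen[k % 2])
    return ids


def make_protocol(
    conditions: Iterable[str],
    reps_per_condition: int,
    n_participants: int,
    seed: int,
    trajectories: Sequence[str] | dict[str, Sequence[str]] | None = None,
    experiment: Literal["exp1", "exp2", "generic"] = "generic",
) -> ProtocolPlan:
    """Build a block-randomized protocol.

    Each participant sees every condition once, in a seeded random order;
    within a condition block, ``reps_per_condition`` trials are planned.
    Trajectory assignment follows the experiment:

    * ``exp1`` — ``trajectories`` is a ``{"L": [...], "R": [...]}`` mapping of
      spine-side pools; two trajectories are drawn per side per block and the
      repetitions split evenly across them (``reps_per_condition`` even).
    * ``exp2``/``generic`` — trajectories drawn with replacement from a flat
      pool (or synthetic ids if none given).

    Identical seeds yield identical plans.
    """
    conditions = list(conditions)
    if not conditions:
        raise ValueError("condition set must be non-empty")
    if reps_per_condition < 1 or n_participants < 1:
        raise ValueError("counts must be >= 1")
    if experiment == "exp1":
        if not isinstance(trajectories, dict):
            raise ValueError("exp1 requires a {'L': [...], 'R': [...]} trajectory pool")
        if reps_per_condition % 2:
            raise ValueError("exp1 splits repetitions over two sides: reps must be even")
    rng = np.random.default_rng(seed)
    participants = []
    for _ in range(n_participants):
        order = list(rng.permutation(np.asarray(conditions, dtype=object)))
        trials: list[TrialSpec] = []
        for cond in order:
            if experiment == "exp1":
                ids = _assign_spine_trajectories(rng, trajectories, reps_per_condition)
            else:
                pool = trajectories if trajectories is not None else [f"traj{i}" for i in range(reps_per_condition)]
                ids = list(rng.choice(np.asarray(pool, dtype=object), size=reps_per_condition, replace=True))
            for rep, tid in enumerate(ids):
                trials.append(TrialSpec(trajectory_id=str(tid), condition=str(cond), repetition=rep))
        participants.append(tuple(trials))
    return ProtocolPlan(participants=tuple(participants), seed=seed)
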