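"""Synthetic stand-ins for the physical study: operator motion, fixtures,
voxel volumes, and whole-study dataset generation.

The operator model is deliberately the simplest motion law with a closed-form
success time: after a dead-time ``latency`` the angular deviation decays
exponentially, ``theta(t) = theta0 * exp(-g (t - latency))``, while the
azimuth performs a small random walk (the tip stays pinned at the trajectory
entry — during angle alignment the instrument only rotates within a
hemisphere). With zero jitter the success event of the 2-s hold rule occurs
at ``latency + ln(theta0/tol)/g + hold``, up to one sample period. It makes
no claim to model human motor control; it exists so the full pipeline can be
exercised and verified without human subjects.

Study-level datasets are drawn directly from the per-condition moments the
study reports (task time and path distance from zero-truncated normals;
questionnaire scores constructed so their scored means match the configured
targets in expectation), ordered by the block-randomized protocol.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import fsolve
from scipy.spatial.transform import Rotation
from scipy.stats import truncnorm

from .geometry import RigidPose, ToolGeometry, Trajectory, axis_from_polar
from .questionnaires import TLX_SUBSCALES
from .session import make_protocol
from .volume import VoxelVolume

__all__ = [
    "EXP1_CONDITIONS",
    "EXP2_CONDITIONS",
    "EXP1_MOMENTS",
    "EXP2_MOMENTS",
    "OperatorModel",
    "PhantomFixture",
    "substream",
    "simulate_alignment",
    "generate_spine_fixture",
    "generate_pyramid_fixture",
    "generate_study_dataset",
    "generate_volume",
]

EXP1_CONDITIONS = ("circle_tmi", "grid_tmi", "traditional_external")
EXP2_CONDITIONS = ("circle_tmi", "grid_tmi", "circle_external", "grid_external")

# Per-condition (mean, std) moments of the spine experiment: task time (s),
# path distance (mm), overall cognitive load and mental demand (TLX, 0-100),
# usability (SUS, 0-100) and the three design Likert scales (1-5).
EXP1_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "circle_tmi": {
        "time": (6.4, 2.4), "distance": (16.2, 7.5),
        "cognitive_load": (23.7, 15.4), "mental_demand": (23.6, 20.1),
        "sus": (79.4, 14.1),
        "visual_appeal": (3.8, 1.1), "intuitiveness": (4.6, 0.5), "interaction": (4.2, 0.9),
    },
    "grid_tmi": {
        "time": (7.5, 3.2), "distance": (20.8, 9.9),
        "cognitive_load": (25.0, 14.4), "mental_demand": (25.8, 19.0),
        "sus": (76.7, 18.1),
        "visual_appeal": (3.7, 1.3), "intuitiveness": (4.2, 0.5), "interaction": (3.6, 0.9),
    },
    "traditional_external": {
        "time": (10.9, 7.3), "distance": (24.0, 16.7),
        "cognitive_load": (35.3, 12.7), "mental_demand": (42.8, 18.3),
        "sus": (68.7, 14.7),
        "visual_appeal": (3.1, 0.9), "intuitiveness": (3.9, 0.7), "interaction": (3.7, 0.9),
    },
}

# The abstract single-entry experiment; questionnaire moments were reported
# per display location (TMI vs external), shared between Circle and Grid.
EXP2_MOMENTS: dict[str, dict[str, tuple[float, float]]] = {
    "circle_tmi": {
        "time": (6.0, 2.2), "distance": (11.2, 5.8),
        "cognitive_load": (32.2, 17.3), "mental_demand": (33.7, 25.3), "sus": (80.8, 13.1),
        "visual_appeal": (4.6, 0.6), "intuitiveness": (4.8, 0.4), "interaction": (4.6, 0.8),
    },
    "grid_tmi": {
        "time": (7.4, 2.9), "distance": (13.7, 7.1),
        "cognitive_load": (32.2, 17.3), "mental_demand": (33.7, 25.3), "sus": (80.8, 13.1),
        "visual_appeal": (3.6, 1.1), "intuitiveness": (4.0, 1.2), "interaction": (3.3, 1.3),
    },
    "circle_external": {
        "time": (5.4, 2.2), "distance": (10.0, 5.4),
        "cognitive_load": (33.3, 17.1), "mental_demand": (36.9, 26.9), "sus": (80.2, 18.1),
        "visual_appeal": (4.6, 0.6), "intuitiveness": (4.8, 0.4), "interaction": (4.6, 0.8),
    },
    "grid_external": {
        "time": (6.3, 2.5), "distance": (11.2, 6.8),
        "cognitive_load": (33.3, 17.1), "mental_demand": (36.9, 26.9), "sus": (80.2, 18.1),
        "visual_appeal": (3.6, 1.1), "intuitiveness": (4.0, 1.2), "interaction": (3.3, 1.3),
    },
}

#: Experience categories and sampling weights for simulated spine-study
#: participants (mostly juniors, a few seniors, as in the study population).
EXPERIENCE_WEIGHTS = {"Never-10": 0.45, "11-50": 0.2, "51-250": 0.2, ">250": 0.15}


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from a single run seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())]))


@dataclass(frozen=True)
class OperatorModel:
    """Synthetic operator converging exponentially onto the planned axis.

    ``gain`` (1/s) sets the convergence rate, ``latency`` (s) the dead time
    before movement starts, ``jitter_sd`` (deg) optional per-sample angular
    noise, ``phi_drift_sd`` (deg) the azimuth random-walk step. The default
    50 Hz sample rate matches the tracking workstation's frame rate.
    """

    gain: float = 0.6
    jitter_sd: float = 0.0
    latency: float = 0.3
    phi_drift_sd: float = 2.0
    sample_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gain <= 0 or self.sample_rate <= 0 or self.jitter_sd < 0:
            raise ValueError("require gain > 0, sample_rate > 0, jitter_sd >= 0")

    def success_time(self, theta0: float, tol: float, hold: float) -> float:
        """Closed-form success time of the noise-free model (s)."""
        return self.latency + np.log(theta0 / tol) / self.gain + hold


@dataclass(frozen=True)
class PhantomFixture:
    """A named set of planned trajectories, optionally with a volume spec."""

    name: str
    trajectories: tuple[Trajectory, ...]
    volume_shape: tuple[int, int, int] | None = None
    volume_spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        ids = [t.id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            raise ValueError("trajectory ids must be unique")

    def by_id(self, tid: str) -> Trajectory:
        for t in self.trajectories:
            if t.id == tid:
                return t
        raise KeyError(tid)

    def sides(self) -> dict[str, list[str]]:
        """Trajectory ids grouped by pedicle side suffix (-L / -R)."""
        pools: dict[str, list[str]] = {"L": [], "R": []}
        for t in self.trajectories:
            if t.id.endswith("-L"):
                pools["L"].append(t.id)
            elif t.id.endswith("-R"):
                pools["R"].append(t.id)
        return pools

    def to_json(self, path: str | Path) -> None:
        payload = {
            "name": self.name,
            "trajectories": [
                {
                    "id": t.id,
                    "entry": t.entry.tolist(),
                    "direction": t.direction.tolist(),
                    "target_depth": t.target_depth,
                }
                for t in self.trajectories
            ],
        }
        if self.volume_shape is not None:
            payload["volume"] = {"shape": list(self.volume_shape), "spacing": list(self.volume_spacing)}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomFixture":
        payload = json.loads(Path(path).read_text())
        vol = payload.get("volume")
        return cls(
            name=payload["name"],
            trajectories=tuple(Trajectory(**t) for t in payload["trajectories"]),
            volume_shape=tuple(vol["shape"]) if vol else None,
            volume_spacing=tuple(vol["spacing"]) if vol else None,
        )


def _pose_for_axis(
    t: float, axis: np.ndarray, entry: np.ndarray, tool: ToolGeometry
) -> RigidPose:
    """Pose whose shaft points along ``axis`` with the tip pinned at ``entry``."""
    s = tool.shaft_axis
    v = np.cross(s, axis)
    c = float(np.dot(s, axis))
    n = np.linalg.norm(v)
    if n < 1e-12:
        rot = Rotation.identity() if c > 0 else Rotation.from_rotvec(np.pi * _any_perp(s))
    else:
        rot = Rotation.from_rotvec(v / n * np.arctan2(n, c))
    p = entry - rot.apply(tool.tip_offset)
    return RigidPose.from_rotation(t, rot, p)


def _any_perp(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    w = w - np.dot(w, v) * v
    return w / np.linalg.norm(w)


def simulate_alignment(
    op: OperatorModel,
    traj: Trajectory,
    theta0: float,
    phi0: float = 0.0,
    tol: float = 1.0,
    hold: float = 2.0,
    tool: ToolGeometry | None = None,
    reference: np.ndarray | None = None,
    max_duration: float = 120.0,
) -> list[RigidPose]:
    """Simulate one angle-alignment trial and return the pose stream.

    The tip stays pinned at the trajectory entry while the deviation decays
    from ``theta0`` (degrees, must exceed ``tol``) per the operator model.
    Sampling runs at ``op.sample_rate`` until the hold has completed (plus a
    few samples of margin) or ``max_duration`` is reached. Deterministic for
    a given ``op.seed``.
    """
    if theta0 <= tol:
        raise ValueError(f"theta0 ({theta0}) must exceed the tolerance ({tol})")
    if tool is None:
        tool = ToolGeometry()
    rng = np.random.default_rng(op.seed)
    dt = 1.0 / op.sample_rate
    poses: list[RigidPose] = []
    phi = float(phi0)
    run_start: float | None = None
    k = 0
    while True:
        t = k * dt
        theta = theta0 * np.exp(-op.gain * max(0.0, t - op.latency))
        if op.jitter_sd > 0:
            theta = abs(theta + rng.normal(0.0, op.jitter_sd))
        phi = (phi + rng.normal(0.0, op.phi_drift_sd)) % 360.0
        axis = axis_from_polar(min(theta, 179.9), phi, traj, reference)
        poses.append(_pose_for_axis(t, axis, traj.entry, tool))
        if theta <= tol:
            if run_start is None:
                run_start = t
            if t - run_start >= hold + 2 * dt:
                break
        else:
            run_start = None
        if t >= max_duration:
            break
        k += 1
    return poses


_SPINE_LEVELS = ("Th11", "Th12", "L1", "L2", "L3", "L4", "L5")
_LEVEL_DEPTHS = {"Th11": 40.0, "Th12": 40.0, "L1": 45.0, "L2": 45.0, "L3": 45.0, "L4": 50.0, "L5": 50.0}


def generate_spine_fixture() -> PhantomFixture:
    """Synthetic lower-spine fixture: levels Th11–L5, one trajectory per pedicle.

    Fourteen trajectories (7 levels x left/right), spread equally on both
    sides of a synthetic spine axis. World frame: +x to the patient's right,
    +y anterior, +z cranial; entries sit posterior-lateral of the midline and
    directions tilt medially (15 deg toward the midline) and slightly
    caudally (5 deg), pointing anteriorly into the bone. Target depths grow
    from 40 mm at the thoracic levels to 50 mm at L4/L5. The geometry uses
    plausible fixed constants, not a patient CT.
    """
    trajectories = []
    medial, caudal = np.radians(15.0), np.radians(5.0)
    for i, level in enumerate(_SPINE_LEVELS):
        z = -30.0 * i
        for side, sx in (("L", -1.0), ("R", 1.0)):
            entry = np.array([sx * 15.0, -20.0, z])
            direction = np.array([-sx * np.sin(medial), np.cos(medial) * np.cos(caudal), -np.sin(caudal)])
            trajectories.append(
                Trajectory(
                    id=f"{level}-{side}",
                    entry=entry,
                    direction=direction / np.linalg.norm(direction),
                    target_depth=_LEVEL_DEPTHS[level],
                )
            )
    return PhantomFixture(
        name="spine",
        trajectories=tuple(trajectories),
        volume_shape=(64, 64, 128),
        volume_spacing=(2.0, 2.0, 2.0),
    )


def generate_pyramid_fixture(n: int = 5, seed: int = 0, cone_half_angle: float = 30.0) -> PhantomFixture:
    """Abstract pyramid fixture: one shared apex entry, random downward paths.

    ``n`` trajectories share the entry at the apex; directions are drawn
    uniformly within a cone of ``cone_half_angle`` degrees about vertical
    (pointing down into the model). Seeded and deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = substream(seed, "pyramid_fixture")
    apex = np.array([0.0, 0.0, 100.0])
    cos_max = np.cos(np.radians(cone_half_angle))
    trajectories = []
    for i in range(n):
        c = rng.uniform(cos_max, 1.0)  # uniform on the spherical cap
        s = np.sqrt(1.0 - c * c)
        ph = rng.uniform(0.0, 2 * np.pi)
        direction = np.array([s * np.cos(ph), s * np.sin(ph), -c])
        trajectories.append(
            Trajectory(id=f"pyr{i}", entry=apex, direction=direction, target_depth=40.0)
        )
    return PhantomFixture(name="pyramid", trajectories=tuple(trajectories))


@lru_cache(maxsize=None)
def _truncnorm_params(mean: float, std: float, low: float, high: float) -> tuple[float, float]:
    """Solve for (loc, scale) so the truncated normal has the target moments.

    Truncation biases the moments of a clipped normal (a zero-truncated
    N(10.9, 7.3) has mean ~11.9), so the underlying parameters are adjusted
    until the truncated mean and std equal the configured values. Falls back
    to the raw parameters when no solution exists (target CV too large for
    the truncation interval)."""

    def resid(x):
        loc, log_scale = x
        scale = np.exp(log_scale)
        a, b = (low - loc) / scale, (high - loc) / scale
        return [
            truncnorm.mean(a, b, loc=loc, scale=scale) - mean,
            truncnorm.std(a, b, loc=loc, scale=scale) - std,
        ]

    sol, info, ier, _ = fsolve(resid, x0=[mean, np.log(std)], full_output=True)
    if ier != 1 or np.max(np.abs(info["fvec"])) > 1e-6 * max(std, 1.0):
        return mean, std
    return float(sol[0]), float(np.exp(sol[1]))


def _truncated_normal(rng: np.random.Generator, mean: float, std: float, size: int, low: float = 0.0, high: float = np.inf) -> np.ndarray:
    if std <= 0:
        raise ValueError("std must be positive")
    loc, scale = _truncnorm_params(float(mean), float(std), float(low), float(high))
    a, b = (low - loc) / scale, (high - loc) / scale
    return truncnorm.rvs(a, b, loc=loc, scale=scale, size=size, random_state=rng)


def _sus_items_for_score(rng: np.random.Generator, target: float) -> list[int]:
    """Ten SUS item values whose score is the achievable value nearest target."""
    k = int(np.clip(round(target / 2.5), 0, 40))  # total item contribution 0..40
    contrib = np.zeros(10, dtype=int)
    remaining = k
    order = rng.permutation(10)
    for idx in order:
        take = int(min(4, remaining, rng.integers(0, 5)))
        contrib[idx] = take
        remaining -= take
    # distribute any leftover greedily
    for idx in order:
        if remaining == 0:
            break
        room = 4 - contrib[idx]
        add = min(room, remaining)
        contrib[idx] += add
        remaining -= add
    return [int(c + 1) if i % 2 == 0 else int(5 - c) for i, c in enumerate(contrib)]


def _discrete_likert(rng: np.random.Generator, mean: float, std: float, size: int) -> np.ndarray:
    return np.clip(np.rint(rng.normal(mean, std, size)), 1, 5).astype(int)


def generate_study_dataset(
    experiment: Literal["exp1", "exp2"],
    n_participants: int | None = None,
    trials_per_condition: int | None = None,
    moments: dict[str, dict[str, tuple[float, float]]] | None = None,
    seed: int = 0,
    distance_family: Literal["truncnorm", "lognormal"] = "truncnorm",
):
    """Generate a full synthetic study: (metric table, questionnaire table).

    Defaults reproduce the study conditions: the spine experiment with 18
    participants x 3 conditions x 8 trials, or the abstract experiment with
    42 participants x 4 conditions x 5 trials. Task times and path distances
    are drawn per trial from zero-truncated normals with the per-condition
    moments (optionally lognormal for the right-skewed distances, matched by
    moments); questionnaire responses are constructed per participant x
    condition so that scored means match the configured targets in
    expectation. Trial order follows the block-randomized protocol. Fully
    deterministic given ``seed``.
    """
    import pandas as pd

    if experiment == "exp1":
        conditions = EXP1_CONDITIONS
        n_participants = 18 if n_participants is None else n_participants
        trials_per_condition = 8 if trials_per_condition is None else trials_per_condition
        moments = EXP1_MOMENTS if moments is None else moments
        fixture = generate_spine_fixture()
        plan = make_protocol(
            conditions, trials_per_condition, n_participants,
            seed=int(substream(seed, "protocol").integers(2**31)),
            trajectories=fixture.sides(), experiment="exp1",
        )
    elif experiment == "exp2":
        conditions = EXP2_CONDITIONS
        n_participants = 42 if n_participants is None else n_participants
        trials_per_condition = 5 if trials_per_condition is None else trials_per_condition
        moments = EXP2_MOMENTS if moments is None else moments
        fixture = generate_pyramid_fixture(n=8, seed=seed)
        plan = make_protocol(
            conditions, trials_per_condition, n_participants,
            seed=int(substream(seed, "protocol").integers(2**31)),
            trajectories=[t.id for t in fixture.trajectories], experiment="exp2",
        )
    else:
        raise ValueError(f"unknown experiment {experiment!r}")
    for cond in conditions:
        for key in ("time", "distance"):
            m, s = moments[cond][key]
            if m <= 0 or s <= 0:
                raise ValueError(f"moments for {cond}/{key} must be positive")

    rng = substream(seed, "dataset")
    exp_rng = substream(seed, "experience")
    levels = list(EXPERIENCE_WEIGHTS)
    weights = np.array(list(EXPERIENCE_WEIGHTS.values()))
    metric_rows = []
    quest_rows = []
    for pid, trials in enumerate(plan.participants):
        participant = f"P{pid:02d}"
        experience = levels[exp_rng.choice(len(levels), p=weights / weights.sum())] if experiment == "exp1" else None
        for cond in plan.condition_order(pid):
            block = [tr for tr in trials if tr.condition == cond]
            tm, ts = moments[cond]["time"]
            dm, ds = moments[cond]["distance"]
            times = _truncated_normal(rng, tm, ts, len(block))
            if distance_family == "lognormal":
                sigma2 = np.log(1.0 + (ds / dm) ** 2)
                dists = rng.lognormal(np.log(dm) - sigma2 / 2, np.sqrt(sigma2), len(block))
            else:
                dists = _truncated_normal(rng, dm, ds, len(block))
            for tr, tt, dd in zip(block, times, dists):
                row = {
                    "participant": participant,
                    "condition": cond,
                    "trajectory_id": tr.trajectory_id,
                    "task_time_s": float(tt),
                    "euclidean_path_mm": float(dd),
                    "success": True,
                }
                if experience is not None:
                    row["experience"] = experience
                metric_rows.append(row)
            # one questionnaire per participant x condition
            sus_target = float(_truncated_normal(rng, *moments[cond]["sus"], 1, 0.0, 100.0)[0])
            sus_items = _sus_items_for_score(rng, sus_target)
            cog_m, cog_s = moments[cond]["cognitive_load"]
            men_m, men_s = moments[cond]["mental_demand"]
            mental = float(_truncated_normal(rng, men_m, men_s, 1, 0.0, 100.0)[0])
            other_mean = np.clip((6 * cog_m - men_m) / 5.0, 0.0, 100.0)
            others = _truncated_normal(rng, other_mean, cog_s, 5, 0.0, 100.0)
            tlx = dict(zip(TLX_SUBSCALES, [mental, *map(float, others)]))
            design = {
                aspect: int(_discrete_likert(rng, *moments[cond][aspect], 1)[0])
                for aspect in ("visual_appeal", "intuitiveness", "interaction")
            }
            qrow = {"participant": participant, "condition": cond}
            qrow.update({f"sus{i+1}": v for i, v in enumerate(sus_items)})
            qrow.update(tlx)
            qrow.update(design)
            quest_rows.append(qrow)
    metric_table = pd.DataFrame(metric_rows)
    if experiment == "exp1":
        from .stats import region_of

        metric_table["region"] = metric_table["trajectory_id"].map(region_of)
    return metric_table, pd.DataFrame(quest_rows)


def generate_volume(
    fixture: PhantomFixture,
    shape: tuple[int, int, int] | None = None,
    spacing: tuple[float, float, float] | None = None,
    pad_mm: float = 40.0,
) -> VoxelVolume:
    """Synthetic voxel volume with bright blocks around the trajectory entries.

    A stand-in for the phantom CT shown by the emulated external view: a
    near-zero background with one bright box ("vertebra") centred on each
    trajectory entry. Deterministic given its inputs.
    """
    shape = shape or fixture.volume_shape or (64, 64, 64)
    spacing = np.asarray(spacing or fixture.volume_spacing or (2.0, 2.0, 2.0), dtype=float)
    if any(s <= 0 for s in shape) or np.any(spacing <= 0):
        raise ValueError("shape and spacing must be positive")
    entries = np.array([t.entry for t in fixture.trajectories])
    lo = entries.min(axis=0) - pad_mm
    data = np.zeros(shape)
    vol = VoxelVolume(data=data, spacing=spacing, origin=lo)
    half_vox = np.maximum(1, (10.0 / spacing).astype(int))  # 10 mm half-width blocks
    for t in fixture.trajectories:
        c = np.round(vol.world_to_voxel(t.entry)).astype(int)
        sl = tuple(
            slice(max(0, c[d] - half_vox[d]), min(shape[d], c[d] + half_vox[d] + 1))
            for d in range(3)
        )
        data[sl] = 1000.0
    return VoxelVolume(data=data, spacing=spacing, origin=lo)
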