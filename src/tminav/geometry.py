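"""Rigid-pose algebra and trajectory-relative polar geometry.

This module holds the geometric core of the navigation system: timestamped
rigid poses of a tracked instrument, the tool-frame constants (tip offset and
shaft axis), planned insertion trajectories, the decomposition of the current
tool axis into an angular deviation ``theta`` and azimuth ``phi`` relative to
the planned direction, the azimuthal projection used by the guidance displays,
signed insertion depth, and least-squares pivot calibration.

Conventions (fixed throughout the package):

* quaternions are ``(w, x, y, z)`` and encode the world-from-tool rotation,
  i.e. ``v_world = R @ v_tool + p``;
* translations are millimetres, timestamps seconds, angles degrees at every
  public interface;
* ``phi`` is measured counter-clockwise in the plane perpendicular to the
  planned direction, viewed looking against that direction, starting at the
  projection of a configurable reference direction; ``phi = 0`` when
  ``theta = 0`` so the polar decomposition is total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "RigidPose",
    "ToolGeometry",
    "Trajectory",
    "PolarOffset",
    "PivotResult",
    "PivotCalibrationError",
    "apply_tool_geometry",
    "angular_deviation",
    "trajectory_frame",
    "polar_offset",
    "axis_from_polar",
    "project_to_display",
    "insertion_depth",
    "pivot_calibrate",
]

_QUAT_TOL = 1e-6


def _as_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError(f"{name} must be a non-zero vector")
    return v / n


@dataclass(frozen=True)
class RigidPose:
    """Timestamped world-from-tool rigid transform.

    Parameters
    ----------
    t : float
        Seconds since stream start; non-negative.
    q : array-like, shape (4,)
        Unit quaternion ``(w, x, y, z)``. Rejected if its norm deviates from
        1 by more than 1e-6; otherwise renormalized.
    p : array-like, shape (3,)
        Tool origin in world coordinates, millimetres.
    """

    t: float
    q: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float).reshape(4)
        p = np.asarray(self.p, dtype=float).reshape(3)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > _QUAT_TOL:
            raise ValueError(
                f"quaternion norm {n:.9f} deviates from 1 by more than {_QUAT_TOL}"
            )
        if self.t < 0:
            raise ValueError("timestamp must be non-negative")
        object.__setattr__(self, "q", q / n)
        object.__setattr__(self, "p", p)

    @property
    def rotation(self) -> Rotation:
        w, x, y, z = self.q
        return Rotation.from_quat([x, y, z, w])  # scipy uses (x, y, z, w)

    @classmethod
    def from_rotation(cls, t: float, rot: Rotation, p: np.ndarray) -> "RigidPose":
        x, y, z, w = rot.as_quat()
        return cls(t=t, q=np.array([w, x, y, z]), p=np.asarray(p, dtype=float))


@dataclass(frozen=True)
class ToolGeometry:
    """Tool-frame constants: tip offset (mm) and unit shaft axis.

    The marker-to-tool calibration is known by construction for the tracked
    handle; these constants express the tooltip and the shaft direction
    (handle toward tip) in the tool frame.
    """

    tip_offset: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 100.0]))
    shaft_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        object.__setattr__(self, "tip_offset", np.asarray(self.tip_offset, dtype=float).reshape(3))
        object.__setattr__(self, "shaft_axis", _as_unit(np.asarray(self.shaft_axis, dtype=float).reshape(3), "shaft_axis"))


@dataclass(frozen=True)
class Trajectory:
    """Planned insertion path: entry point, unit direction, target depth (mm)."""

    id: str
    entry: np.ndarray
    direction: np.ndarray
    target_depth: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "entry", np.asarray(self.entry, dtype=float).reshape(3))
        object.__setattr__(self, "direction", _as_unit(np.asarray(self.direction, dtype=float).reshape(3), "direction"))
        if not self.target_depth > 0:
            raise ValueError("target_depth must be positive")


@dataclass(frozen=True)
class PolarOffset:
    """Angular deviation ``theta`` and azimuth ``phi`` in degrees.

    ``theta`` is in [0, 180]; ``phi`` in [0, 360), with ``phi = 0`` by
    convention when ``theta = 0``.
    """

    theta: float
    phi: float

    def __post_init__(self) -> None:
        if self.theta < 0 or self.theta > 180:
            raise ValueError("theta must be in [0, 180] degrees")
        object.__setattr__(self, "phi", float(self.phi) % 360.0 if self.theta > 0 else 0.0)


@dataclass(frozen=True)
class PivotResult:
    """Pivot-calibration output: tool-frame tip offset, world pivot point, rms residual (mm)."""

    tip_offset: np.ndarray
    pivot_point: np.ndarray
    rms_residual: float


class PivotCalibrationError(ValueError):
    """Raised when the pivot system is under-determined or rank-deficient."""


def apply_tool_geometry(pose: RigidPose, tool: ToolGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Map the tool-frame tip and shaft axis into world coordinates.

    Returns ``(tip, axis)`` with ``tip = R @ tip_offset + p`` (mm) and
    ``axis = R @ shaft_axis`` renormalized to unit length.
    """
    R = pose.rotation
    tip = R.apply(tool.tip_offset) + pose.p
    axis = R.apply(tool.shaft_axis)
    return tip, axis / np.linalg.norm(axis)


def angular_deviation(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two directions, in degrees in [0, 180].

    Symmetric and invariant under positive scaling of either argument.
    Uses the numerically stable atan2 form rather than a clipped arccos.
    """
    u = _as_unit(np.asarray(u, dtype=float), "u")
    v = _as_unit(np.asarray(v, dtype=float), "v")
    return float(np.degrees(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v))))


def trajectory_frame(direction: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal in-plane basis ``(e1, e2)`` perpendicular to ``direction``.

    ``e1`` is the normalized projection of ``reference`` onto the plane;
    ``e2 = direction x e1`` completes a right-handed frame so that azimuths
    increase counter-clockwise when viewed against ``direction``.
    """
    d = _as_unit(direction, "direction")
    r = np.asarray(reference, dtype=float)
    r_perp = r - np.dot(r, d) * d
    n = np.linalg.norm(r_perp)
    if n < 1e-9 * max(np.linalg.norm(r), 1.0):
        raise ValueError("reference direction is parallel to the trajectory direction")
    e1 = r_perp / n
    e2 = np.cross(d, e1)
    return e1, e2


DEFAULT_REFERENCE = np.array([1.0, 0.0, 0.0])


def polar_offset(
    axis: np.ndarray,
    traj: Trajectory,
    reference: np.ndarray | None = None,
) -> PolarOffset:
    """Decompose a world tool axis into (theta, phi) about the planned direction.

    ``theta`` is the angular deviation from ``traj.direction``; ``phi`` the
    azimuth of the deviation in the perpendicular plane, measured from the
    projected ``reference`` direction (default world +x).
    """
    if reference is None:
        reference = DEFAULT_REFERENCE
    a = _as_unit(axis, "axis")
    d = traj.direction
    theta = angular_deviation(a, d)
    if theta == 0.0:
        return PolarOffset(theta=0.0, phi=0.0)
    e1, e2 = trajectory_frame(d, reference)
    phi = np.degrees(np.arctan2(np.dot(a, e2), np.dot(a, e1))) % 360.0
    return PolarOffset(theta=theta, phi=float(phi))


def axis_from_polar(
    theta: float,
    phi: float,
    traj: Trajectory,
    reference: np.ndarray | None = None,
) -> np.ndarray:
    """Reconstruct the world axis with deviation ``theta`` and azimuth ``phi``.

    Inverse of :func:`polar_offset` for theta < 180.
    """
    if reference is None:
        reference = DEFAULT_REFERENCE
    d = traj.direction
    e1, e2 = trajectory_frame(d, reference)
    th, ph = np.radians(theta), np.radians(phi)
    return np.cos(th) * d + np.sin(th) * (np.cos(ph) * e1 + np.sin(ph) * e2)


def project_to_display(offset: PolarOffset, cfg) -> tuple[float, float]:
    """Equidistant azimuthal projection of a polar offset to display coordinates.

    The radius grows linearly with theta (raised to ``cfg.sensitivity_gamma``
    on the normalized scale, 1.0 by default) and clamps at ``cfg.theta_max_deg``,
    so the display edge corresponds to a fixed angular deviation:
    ``r = R * (min(theta, theta_max)/theta_max)**gamma``,
    ``(x, y) = (r cos phi, r sin phi)``.
    """
    theta_max = cfg.theta_max_deg
    gamma = getattr(cfg, "sensitivity_gamma", 1.0)
    frac = min(offset.theta, theta_max) / theta_max
    r = cfg.radius * frac**gamma
    ph = np.radians(offset.phi)
    return float(r * np.cos(ph)), float(r * np.sin(ph))


def insertion_depth(tip: np.ndarray, traj: Trajectory) -> float:
    """Signed depth (mm) of the tip along the planned direction from the entry.

    Lateral displacement perpendicular to the direction does not change the
    value; negative values mean the tip is short of the entry plane.
    """
    return float(np.dot(np.asarray(tip, dtype=float) - traj.entry, traj.direction))


def pivot_calibrate(poses: Sequence[RigidPose]) -> PivotResult:
    """Estimate the tool-frame tip offset by pivoting the tip about a fixed point.

    Solves the stacked linear least-squares system ``R_i t_tip + p_i = p_pivot``
    in the six unknowns (tip offset, pivot point). Requires at least three
    poses with rotational diversity: if all rotations share one axis through
    the pivot, a component of the solution is unobservable and the system is
    rank-deficient.

    Raises
    ------
    PivotCalibrationError
        For fewer than three poses or a (numerically) rank-deficient system.
    """
    if len(poses) < 3:
        raise PivotCalibrationError(
            f"pivot calibration needs at least 3 poses, got {len(poses)}"
        )
    n = len(poses)
    A = np.zeros((3 * n, 6))
    b = np.zeros(3 * n)
    for i, pose in enumerate(poses):
        A[3 * i : 3 * i + 3, :3] = pose.rotation.as_matrix()
        A[3 * i : 3 * i + 3, 3:] = -np.eye(3)
        b[3 * i : 3 * i + 3] = -pose.p
    sol, _, rank, sv = np.linalg.lstsq(A, b, rcond=None)
    if rank < 6 or sv[-1] < 1e-8 * sv[0]:
        raise PivotCalibrationError(
            "rank-deficient pivot system (singular values "
            f"{sv.round(6).tolist()}): rotations lack diversity — pivot about "
            "more than one axis"
        )
    tip_offset, pivot = sol[:3], sol[3:]
    res = (A @ sol - b).reshape(n, 3)
    rms = float(np.sqrt(np.mean(np.sum(res**2, axis=1))))
    return PivotResult(tip_offset=tip_offset, pivot_point=pivot, rms_residual=rms)
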