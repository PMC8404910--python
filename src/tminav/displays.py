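"""Renderer-agnostic state models for the guidance displays.

Four views are modelled, all as pure functions of the current polar offset
(or insertion depth) and a :class:`DisplayConfig`:

* **Circle** — a single moving element on a circular display; entering the
  centre ring (deviation within tolerance) flips it from yellow to blue and
  switches on a highlight around the centre.
* **Grid** — the display face partitioned into ``n_sectors`` angular segments
  crossed with ``n_rings`` concentric rings; the patch containing the current
  tool offset is flagged red, and the centre circle turns green once the
  deviation is within tolerance.
* **Depth** — concentric rings that light up one by one as the tool advances
  toward the planned hole depth; the innermost element turns from white to
  green when the target depth is reached.
* **Traditional external** — an emulated three-plane slice view of a volume
  through the tooltip, with the planned path drawn red and the current tool
  axis green on each plane.

States carry no hidden state and no rendering code; a flat scene-primitive
export is provided for any renderer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.ndimage import map_coordinates

from .geometry import PolarOffset, Trajectory, project_to_display
from .volume import VoxelVolume

__all__ = [
    "DisplayConfig",
    "CircleState",
    "GridState",
    "DepthState",
    "SliceView",
    "update_circle",
    "grid_cell",
    "update_grid",
    "update_depth",
    "traditional_slices",
    "scene_primitives",
]


@dataclass(frozen=True)
class DisplayConfig:
    """Geometry, thresholds and colour scheme shared by the displays.

    ``tolerance_deg`` is the in-target angular threshold (inclusive);
    ``theta_max_deg`` the deviation mapped to the display edge. The grid uses
    ``n_sectors`` equal angular segments starting at azimuth 0 and
    ``n_rings`` equal-width theta bins between tolerance and theta_max.
    ``sensitivity_gamma`` < 1 gives higher movement sensitivity close to the
    target (used by the updated Circle preset); 1.0 is the linear default.
    """

    tolerance_deg: float = 1.0
    theta_max_deg: float = 45.0
    radius: float = 1.0
    n_sectors: int = 12
    n_rings: int = 4
    n_depth_rings: int = 4
    depth_tol_mm: float = 0.5
    element_radius: float = 0.12
    sensitivity_gamma: float = 1.0
    overshoot_warning: bool = False
    circle_out_color: str = "yellow"
    circle_in_color: str = "blue"
    grid_flag_color: str = "red"
    center_color: str = "green"
    depth_pending_color: str = "white"
    depth_done_color: str = "green"

    def __post_init__(self) -> None:
        if not 0 < self.tolerance_deg < self.theta_max_deg:
            raise ValueError("require 0 < tolerance_deg < theta_max_deg")
        if self.n_sectors < 1 or self.n_rings < 1 or self.n_depth_rings < 1:
            raise ValueError("sector/ring counts must be >= 1")

    @classmethod
    def updated_circle(cls, **overrides) -> "DisplayConfig":
        """Preset for the revised Circle design driven by participant feedback:
        smaller moving element, red/green colour scheme, and nonlinear
        sensitivity that magnifies movement near the target."""
        defaults = dict(
            element_radius=0.06,
            sensitivity_gamma=0.5,
            circle_out_color="red",
            circle_in_color="green",
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass(frozen=True)
class CircleState:
    position: tuple[float, float]
    in_target: bool
    element_color: str
    highlight: bool


@dataclass(frozen=True)
class GridState:
    flagged_cell: Literal["center"] | tuple[int, int]
    center_green: bool


@dataclass(frozen=True)
class DepthState:
    rings_lit: int
    reached: bool
    overshoot: bool


@dataclass(frozen=True)
class SliceView:
    """One resampled plane of the emulated external view.

    ``image[r, c]`` samples the volume at
    ``origin + u(c) * e_u + v(r) * e_v`` where u, v span
    ``[-half_size, half_size]`` mm. Segments are (2, 2) arrays of (u, v)
    slice coordinates after clipping, or None if fully outside.
    """

    plane: str
    origin: np.ndarray
    normal: np.ndarray
    e_u: np.ndarray
    e_v: np.ndarray
    half_size: float
    image: np.ndarray
    planned_segment: np.ndarray | None
    current_segment: np.ndarray | None


def update_circle(offset: PolarOffset, cfg: DisplayConfig) -> CircleState:
    """Circle-display state for a polar offset.

    The moving element sits at the projected offset; within tolerance
    (inclusive) it is blue with the centre highlight on, otherwise yellow.
    """
    in_target = offset.theta <= cfg.tolerance_deg
    return CircleState(
        position=project_to_display(offset, cfg),
        in_target=in_target,
        element_color=cfg.circle_in_color if in_target else cfg.circle_out_color,
        highlight=in_target,
    )


def grid_cell(offset: PolarOffset, cfg: DisplayConfig) -> Literal["center"] | tuple[int, int]:
    """Grid cell containing a polar offset: ``"center"`` or ``(sector, ring)``.

    Sector 0 starts at phi = 0 (the reference direction) and sectors advance
    counter-clockwise; ring bins are equal-width in theta between
    tolerance_deg and theta_max_deg, with theta >= theta_max clamped into the
    outermost ring.
    """
    if offset.theta <= cfg.tolerance_deg:
        return "center"
    sector = int(offset.phi // (360.0 / cfg.n_sectors)) % cfg.n_sectors
    ring_width = (cfg.theta_max_deg - cfg.tolerance_deg) / cfg.n_rings
    ring = min(cfg.n_rings - 1, int((offset.theta - cfg.tolerance_deg) // ring_width))
    return sector, ring


def update_grid(offset: PolarOffset, cfg: DisplayConfig) -> GridState:
    """Grid-display state: exactly one cell flagged; centre green iff in target."""
    cell = grid_cell(offset, cfg)
    return GridState(flagged_cell=cell, center_green=cell == "center")


def update_depth(depth: float, traj: Trajectory, cfg: DisplayConfig) -> DepthState:
    """Depth-display state from a signed insertion depth (mm).

    Rings light one by one in proportion to depth/target_depth; ``reached``
    fires within ``depth_tol_mm`` of the target, ``overshoot`` (an optional
    warning) beyond it.
    """
    frac = depth / traj.target_depth
    rings = int(np.clip(np.floor(cfg.n_depth_rings * frac), 0, cfg.n_depth_rings))
    reached = depth >= traj.target_depth - cfg.depth_tol_mm
    if reached:
        rings = cfg.n_depth_rings
    overshoot = reached and depth > traj.target_depth + cfg.depth_tol_mm
    return DepthState(rings_lit=rings, reached=reached, overshoot=overshoot)


def _clip_segment(a: np.ndarray, b: np.ndarray, half: float) -> np.ndarray | None:
    """Liang–Barsky clip of segment a-b to the square [-half, half]^2."""
    d = b - a
    t0, t1 = 0.0, 1.0
    for dim in range(2):
        for sign in (-1.0, 1.0):
            p = sign * d[dim]
            q = half - sign * a[dim]
            if p == 0.0:
                if q < 0:
                    return None
            else:
                t = q / p
                if p < 0:
                    t0 = max(t0, t)
                else:
                    t1 = min(t1, t)
    if t0 > t1:
        return None
    return np.vstack([a + t0 * d, a + t1 * d])


def _project_line(
    point: np.ndarray,
    direction: np.ndarray,
    length: float,
    origin: np.ndarray,
    e_u: np.ndarray,
    e_v: np.ndarray,
    half: float,
) -> np.ndarray | None:
    """Orthogonally project a 3-D segment onto the slice plane and clip it."""
    a3 = np.asarray(point, dtype=float)
    b3 = a3 + length * np.asarray(direction, dtype=float)
    a = np.array([np.dot(a3 - origin, e_u), np.dot(a3 - origin, e_v)])
    b = np.array([np.dot(b3 - origin, e_u), np.dot(b3 - origin, e_v)])
    return _clip_segment(a, b, half)


_ANATOMICAL_PLANES = {
    # plane name -> (normal axis, in-plane u axis, in-plane v axis), world frame
    "axial": (2, 0, 1),
    "coronal": (1, 0, 2),
    "sagittal": (0, 1, 2),
}


def traditional_slices(
    volume: VoxelVolume,
    tip: np.ndarray,
    axis: np.ndarray,
    traj: Trajectory,
    mode: Literal["anatomical", "tool_axes"] = "anatomical",
    tool_rotation=None,
    half_size: float = 40.0,
    n_px: int = 64,
    segment_length: float = 80.0,
) -> list[SliceView]:
    """Emulated three-plane external view through the tooltip.

    Resamples the volume on three planes through ``tip`` — the anatomical
    axial/coronal/sagittal planes, or planes normal to the tool frame axes
    (``mode="tool_axes"``, requires ``tool_rotation``, a scipy Rotation).
    On each plane the planned path is drawn from the trajectory entry along
    its direction and the current tool axis from the tip; both segments are
    orthogonal projections of the 3-D lines, clipped to the slice bounds.
    The planned orientation is attained when the red (planned) and green
    (current) lines coincide on all three planes.
    """
    tip = np.asarray(tip, dtype=float)
    if not volume.contains(tip):
        raise ValueError(f"tip {tip.tolist()} lies outside the volume bounds")
    if mode == "anatomical":
        eye = np.eye(3)
        frames = [(name, eye[k], eye[u], eye[v]) for name, (k, u, v) in _ANATOMICAL_PLANES.items()]
    elif mode == "tool_axes":
        if tool_rotation is None:
            raise ValueError("tool_axes mode requires tool_rotation")
        R = tool_rotation.as_matrix()
        frames = [
            ("toolX", R[:, 0], R[:, 1], R[:, 2]),
            ("toolY", R[:, 1], R[:, 2], R[:, 0]),
            ("toolZ", R[:, 2], R[:, 0], R[:, 1]),
        ]
    else:
        raise ValueError(f"unknown slice mode: {mode!r}")

    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    views = []
    coords_1d = np.linspace(-half_size, half_size, n_px)
    for name, normal, e_u, e_v in frames:
        uu, vv = np.meshgrid(coords_1d, coords_1d)  # vv indexes rows
        pts = tip + uu[..., None] * e_u + vv[..., None] * e_v
        idx = volume.world_to_voxel(pts.reshape(-1, 3)).T
        img = map_coordinates(volume.data, idx, order=1, cval=0.0).reshape(n_px, n_px)
        planned = _project_line(traj.entry, traj.direction, segment_length, tip, e_u, e_v, half_size)
        current = _project_line(tip, axis, segment_length, tip, e_u, e_v, half_size)
        views.append(
            SliceView(
                plane=name,
                origin=tip,
                normal=normal,
                e_u=e_u,
                e_v=e_v,
                half_size=half_size,
                image=img,
                planned_segment=planned,
                current_segment=current,
            )
        )
    return views


def scene_primitives(state, cfg: DisplayConfig) -> list[dict]:
    """Flatten a display state into renderer-agnostic drawing primitives.

    Returns a list of dicts (``circle``, ``annulus_sector``, ``segment``)
    with colour names and display-unit coordinates, serializable to JSON.
    """
    prims: list[dict] = []
    if isinstance(state, CircleState):
        prims.append({"kind": "circle", "center": [0.0, 0.0], "r": cfg.radius, "color": "background", "fill": False})
        tol_r = cfg.radius * (cfg.tolerance_deg / cfg.theta_max_deg) ** cfg.sensitivity_gamma
        prims.append({"kind": "circle", "center": [0.0, 0.0], "r": tol_r, "color": "green" if state.highlight else "gray", "fill": False})
        prims.append({"kind": "circle", "center": list(state.position), "r": cfg.element_radius, "color": state.element_color, "fill": True})
    elif isinstance(state, GridState):
        ring_edges = np.linspace(cfg.tolerance_deg, cfg.theta_max_deg, cfg.n_rings + 1)
        to_r = lambda th: cfg.radius * (th / cfg.theta_max_deg) ** cfg.sensitivity_gamma
        for s in range(cfg.n_sectors):
            for r in range(cfg.n_rings):
                flagged = state.flagged_cell == (s, r)
                prims.append(
                    {
                        "kind": "annulus_sector",
                        "r_inner": to_r(ring_edges[r]),
                        "r_outer": to_r(ring_edges[r + 1]),
                        "phi_start": s * 360.0 / cfg.n_sectors,
                        "phi_end": (s + 1) * 360.0 / cfg.n_sectors,
                        "color": cfg.grid_flag_color if flagged else "background",
                        "fill": flagged,
                    }
                )
        prims.append(
            {
                "kind": "circle",
                "center": [0.0, 0.0],
                "r": to_r(cfg.tolerance_deg),
                "color": cfg.center_color if state.center_green else "background",
                "fill": state.center_green,
            }
        )
    elif isinstance(state, DepthState):
        for i in range(cfg.n_depth_rings):
            lit = i < state.rings_lit
            prims.append(
                {
                    "kind": "circle",
                    "center": [0.0, 0.0],
                    "r": cfg.radius * (cfg.n_depth_rings - i) / (cfg.n_depth_rings + 1),
                    "color": cfg.depth_done_color if lit else cfg.depth_pending_color,
                    "fill": lit,
                }
            )
        prims.append(
            {
                "kind": "circle",
                "center": [0.0, 0.0],
                "r": cfg.radius / (cfg.n_depth_rings + 1) * 0.8,
                "color": cfg.depth_done_color if state.reached else cfg.depth_pending_color,
                "fill": True,
            }
        )
        if cfg.overshoot_warning and state.overshoot:
            prims.append({"kind": "circle", "center": [0.0, 0.0], "r": cfg.radius, "color": "red", "fill": False})
    elif isinstance(state, SliceView):
        for seg, color in ((state.planned_segment, "red"), (state.current_segment, "green")):
            if seg is not None:
                prims.append({"kind": "segment", "a": seg[0].tolist(), "b": seg[1].tolist(), "color": color})
    else:
        raise TypeError(f"no primitive export for {type(state).__name__}")
    return prims
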