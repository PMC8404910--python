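"""Display-state models: circle, grid partition, depth rings, slice views."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from tminav import (
    DisplayConfig,
    PolarOffset,
    Trajectory,
    grid_cell,
    scene_primitives,
    traditional_slices,
    update_circle,
    update_depth,
    update_grid,
)
from tminav.simulate import generate_spine_fixture, generate_volume


def brute_force_cell(theta, phi, cfg):
    """Independent binning oracle: scan the bin edges directly."""
    if theta <= cfg.tolerance_deg:
        return "center"
    sector_width = 360.0 / cfg.n_sectors
    sector = next(s for s in range(cfg.n_sectors) if s * sector_width <= phi < (s + 1) * sector_width)
    edges = np.linspace(cfg.tolerance_deg, cfg.theta_max_deg, cfg.n_rings + 1)
    for r in range(cfg.n_rings):
        if edges[r] <= theta < edges[r + 1]:
            return sector, r
    return sector, cfg.n_rings - 1


class TestCircle:
    def test_aligned(self, cfg):
        s = update_circle(PolarOffset(0, 0), cfg)
        assert s.position == (0.0, 0.0)
        assert s.in_target and s.element_color == "blue" and s.highlight

    def test_outside_tolerance_yellow(self, cfg):
        s = update_circle(PolarOffset(2 * cfg.tolerance_deg, 10), cfg)
        assert not s.in_target and s.element_color == "yellow" and not s.highlight

    def test_boundary_inclusive(self, cfg):
        assert update_circle(PolarOffset(cfg.tolerance_deg, 10), cfg).in_target

    def test_updated_circle_preset(self):
        cfg = DisplayConfig.updated_circle()
        s_out = update_circle(PolarOffset(10, 0), cfg)
        assert s_out.element_color == "red"
        s_in = update_circle(PolarOffset(0.5, 0), cfg)
        assert s_in.element_color == "green"
        # gamma < 1: small deviations displace more than linearly
        x, _ = s_out.position
        assert x > cfg.radius * 10 / cfg.theta_max_deg


class TestGridCell:
    def test_center_within_tolerance(self, cfg):
        assert grid_cell(PolarOffset(0.5, 123), cfg) == "center"

    def test_spec_bin_examples(self):
        cfg = DisplayConfig(tolerance_deg=2.0, theta_max_deg=30.0)
        assert grid_cell(PolarOffset(10, 45), cfg) == (1, 1)
        assert grid_cell(PolarOffset(29.9, 359.9), cfg) == (11, 3)

    def test_beyond_theta_max_clamps_to_outer_ring(self, cfg):
        s, r = grid_cell(PolarOffset(170, 10), cfg)
        assert r == cfg.n_rings - 1

    def test_sweep_phi_visits_each_sector_once(self, cfg):
        seen = []
        for phi in np.arange(0, 360, 0.1):
            cell = grid_cell(PolarOffset(20, phi), cfg)
            if not seen or cell != seen[-1]:
                seen.append(cell)
        sectors = [c[0] for c in seen]
        assert sectors == list(range(cfg.n_sectors))

    def test_agreement_with_brute_force_binning(self, cfg, rng):
        thetas = rng.uniform(0, 180, 2000)
        phis = rng.uniform(0, 360, 2000)
        for th, ph in zip(thetas, phis):
            off = PolarOffset(th, ph)
            assert grid_cell(off, cfg) == brute_force_cell(off.theta, off.phi, cfg)

    @settings(deadline=None, derandomize=True)
    @given(theta=st.floats(0, 180), phi=st.floats(0, 359.999))
    def test_partition_total(self, theta, phi):
        cfg = DisplayConfig()
        cell = grid_cell(PolarOffset(theta, phi), cfg)
        if cell != "center":
            s, r = cell
            assert 0 <= s < cfg.n_sectors and 0 <= r < cfg.n_rings


class TestGridState:
    def test_center_green_when_aligned(self, cfg):
        s = update_grid(PolarOffset(0, 0), cfg)
        assert s.flagged_cell == "center" and s.center_green

    def test_one_red_patch_otherwise(self, cfg):
        s = update_grid(PolarOffset(12, 200), cfg)
        assert isinstance(s.flagged_cell, tuple) and not s.center_green

    def test_coherence_with_circle(self, cfg, rng):
        for th in rng.uniform(0, 5, 200):
            off = PolarOffset(th, 45)
            assert update_circle(off, cfg).in_target == update_grid(off, cfg).center_green


class TestDepth:
    def test_zero_depth(self, traj_z, cfg):
        s = update_depth(0.0, traj_z, cfg)
        assert s.rings_lit == 0 and not s.reached and not s.overshoot

    def test_target_depth_reached(self, traj_z, cfg):
        s = update_depth(traj_z.target_depth, traj_z, cfg)
        assert s.rings_lit == cfg.n_depth_rings and s.reached and not s.overshoot

    def test_half_depth_lights_half_rings(self, traj_z, cfg):
        assert update_depth(0.5 * traj_z.target_depth, traj_z, cfg).rings_lit == 2

    def test_overshoot_implies_reached(self, traj_z, cfg):
        s = update_depth(traj_z.target_depth + 5, traj_z, cfg)
        assert s.overshoot and s.reached

    def test_rings_monotone_in_depth(self, traj_z, cfg):
        depths = np.linspace(-10, 60, 300)
        rings = [update_depth(d, traj_z, cfg).rings_lit for d in depths]
        assert np.all(np.diff(rings) >= 0)


class TestPurity:
    def test_states_are_pure_functions(self, cfg, traj_z):
        off = PolarOffset(7.3, 211.0)
        assert update_circle(off, cfg) == update_circle(off, cfg)
        assert update_grid(off, cfg) == update_grid(off, cfg)
        assert update_depth(13.0, traj_z, cfg) == update_depth(13.0, traj_z, cfg)


@pytest.fixture(scope="module")
def volume():
    return generate_volume(generate_spine_fixture())


class TestTraditionalSlices:
    def test_three_planes_through_tip(self, volume):
        traj = generate_spine_fixture().trajectories[0]
        views = traditional_slices(volume, traj.entry, traj.direction, traj)
        assert [v.plane for v in views] == ["axial", "coronal", "sagittal"]
        for v in views:
            assert v.image.shape == (64, 64)
            # the tip voxel (slice centre) sits inside a bright vertebra block
            assert v.image[32, 32] > 0

    def test_in_plane_line_preserves_length(self, volume):
        traj = generate_spine_fixture().trajectories[0]
        tip = traj.entry
        axis = np.array([1.0, 0.0, 0.0])  # lies in the axial plane
        views = traditional_slices(volume, tip, axis, traj, segment_length=30.0)
        axial = views[0]
        seg = axial.current_segment
        assert np.linalg.norm(seg[1] - seg[0]) == pytest.approx(30.0, abs=1e-9)

    def test_perpendicular_line_degenerates_to_point(self, volume):
        traj = generate_spine_fixture().trajectories[0]
        views = traditional_slices(volume, traj.entry, np.array([0.0, 0.0, 1.0]), traj, segment_length=30.0)
        axial = views[0]  # normal +z: a +z line projects to a point
        seg = axial.current_segment
        assert np.linalg.norm(seg[1] - seg[0]) == pytest.approx(0.0, abs=1e-9)

    def test_tip_outside_volume_rejected(self, volume):
        traj = generate_spine_fixture().trajectories[0]
        with pytest.raises(ValueError, match="outside"):
            traditional_slices(volume, np.array([1e4, 0, 0]), traj.direction, traj)

    def test_tool_axes_mode(self, volume):
        traj = generate_spine_fixture().trajectories[0]
        views = traditional_slices(
            volume, traj.entry, traj.direction, traj,
            mode="tool_axes", tool_rotation=Rotation.identity(),
        )
        assert [v.plane for v in views] == ["toolX", "toolY", "toolZ"]


class TestSceneExport:
    def test_primitives_serializable(self, cfg, traj_z):
        import json

        for state in (
            update_circle(PolarOffset(5, 45), cfg),
            update_grid(PolarOffset(5, 45), cfg),
            update_depth(20.0, traj_z, cfg),
        ):
            prims = scene_primitives(state, cfg)
            assert json.dumps(prims)
            assert all("kind" in p and "color" in p for p in prims)

    def test_grid_scene_has_one_flagged_patch(self, cfg):
        prims = scene_primitives(update_grid(PolarOffset(10, 100), cfg), cfg)
        flagged = [p for p in prims if p.get("fill") and p["color"] == cfg.grid_flag_color]
        assert len(flagged) == 1
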