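"""Synthetic operator, fixtures, study datasets and volumes."""

import numpy as np
import pytest

from tminav import (
    OperatorModel,
    ToolGeometry,
    apply_tool_geometry,
    generate_pyramid_fixture,
    generate_spine_fixture,
    generate_study_dataset,
    generate_volume,
    polar_offset,
    run_trial,
    simulate_alignment,
)
from tminav.simulate import EXP1_MOMENTS, _truncnorm_params, substream


class TestSimulateAlignment:
    def test_success_time_matches_closed_form(self, traj_z, tool):
        op = OperatorModel(gain=0.6, latency=0.3, seed=0)
        stream = simulate_alignment(op, traj_z, theta0=15.0, tol=1.0, hold=2.0, tool=tool)
        res = run_trial(stream, traj_z, tool, tolerance_deg=1.0, hold_duration=2.0)
        assert res.success
        assert res.task_time == pytest.approx(op.success_time(15.0, 1.0, 2.0), abs=1 / op.sample_rate)

    def test_same_seed_identical_streams(self, traj_z, tool):
        op = OperatorModel(seed=42)
        s1 = simulate_alignment(op, traj_z, theta0=10.0, tool=tool)
        s2 = simulate_alignment(op, traj_z, theta0=10.0, tool=tool)
        assert len(s1) == len(s2)
        for a, b in zip(s1, s2):
            assert a.t == b.t and np.array_equal(a.q, b.q) and np.array_equal(a.p, b.p)

    def test_theta_strictly_decreasing_without_jitter(self, traj_z, tool):
        op = OperatorModel(gain=0.8, latency=0.0, jitter_sd=0.0, seed=1)
        stream = simulate_alignment(op, traj_z, theta0=20.0, tol=1.0, tool=tool)
        thetas = [polar_offset(apply_tool_geometry(p, tool)[1], traj_z).theta for p in stream]
        above_tol = [t for t in thetas if t > 1.0]
        assert np.all(np.diff(above_tol) < 0)

    def test_tip_pinned_at_entry(self, traj_z, tool):
        op = OperatorModel(seed=2)
        stream = simulate_alignment(op, traj_z, theta0=25.0, tool=tool)
        for pose in stream[:: max(1, len(stream) // 10)]:
            tip, _ = apply_tool_geometry(pose, tool)
            np.testing.assert_allclose(tip, traj_z.entry, atol=1e-9)

    def test_theta0_below_tolerance_rejected(self, traj_z):
        with pytest.raises(ValueError, match="exceed"):
            simulate_alignment(OperatorModel(), traj_z, theta0=0.5, tol=1.0)

    @pytest.mark.parametrize("theta0", [5.0, 15.0, 30.0])
    def test_end_to_end_success_at_default_settings(self, theta0, traj_z, tool):
        op = OperatorModel(seed=3)
        stream = simulate_alignment(op, traj_z, theta0=theta0, tol=1.0, hold=2.0, tool=tool)
        res = run_trial(stream, traj_z, tool, tolerance_deg=1.0, hold_duration=2.0)
        assert res.success
        assert res.task_time == pytest.approx(op.success_time(theta0, 1.0, 2.0), abs=1 / op.sample_rate)

    def test_gain_recovered_by_log_regression(self, traj_z, tool):
        op = OperatorModel(gain=0.7, latency=0.2, jitter_sd=0.0, phi_drift_sd=0.0, seed=4)
        stream = simulate_alignment(op, traj_z, theta0=20.0, tol=1.0, tool=tool)
        ts, logths = [], []
        for pose in stream:
            theta = polar_offset(apply_tool_geometry(pose, tool)[1], traj_z).theta
            if theta > 1.0 and pose.t > op.latency:
                ts.append(pose.t)
                logths.append(np.log(theta))
        slope = np.polyfit(ts, logths, 1)[0]
        assert -slope == pytest.approx(op.gain, abs=1e-6)


class TestFixtures:
    def test_spine_has_14_unique_trajectories(self):
        f = generate_spine_fixture()
        assert len(f.trajectories) == 14
        assert len({t.id for t in f.trajectories}) == 14

    def test_spine_levels_and_sides(self):
        f = generate_spine_fixture()
        levels = {t.id.rsplit("-", 1)[0] for t in f.trajectories}
        assert levels == {"Th11", "Th12", "L1", "L2", "L3", "L4", "L5"}
        sides = f.sides()
        assert len(sides["L"]) == 7 and len(sides["R"]) == 7

    def test_spine_directions_unit_length(self):
        for t in generate_spine_fixture().trajectories:
            assert np.linalg.norm(t.direction) == pytest.approx(1.0, abs=1e-12)

    def test_pyramid_shares_one_entry(self):
        f = generate_pyramid_fixture(n=6, seed=1)
        entries = {tuple(t.entry) for t in f.trajectories}
        assert len(entries) == 1

    def test_pyramid_directions_within_cone(self):
        f = generate_pyramid_fixture(n=50, seed=2, cone_half_angle=30.0)
        down = np.array([0, 0, -1.0])
        for t in f.trajectories:
            ang = np.degrees(np.arccos(np.clip(np.dot(t.direction, down), -1, 1)))
            assert ang <= 30.0 + 1e-9

    def test_pyramid_seed_deterministic(self):
        a = generate_pyramid_fixture(n=4, seed=9)
        b = generate_pyramid_fixture(n=4, seed=9)
        for ta, tb in zip(a.trajectories, b.trajectories):
            assert np.array_equal(ta.direction, tb.direction)

    def test_fixture_json_roundtrip(self, tmp_path):
        from tminav import PhantomFixture

        f = generate_spine_fixture()
        path = tmp_path / "spine.json"
        f.to_json(path)
        g = PhantomFixture.from_json(path)
        assert g.name == f.name and len(g.trajectories) == 14
        np.testing.assert_allclose(g.trajectories[0].direction, f.trajectories[0].direction)


class TestStudyDataset:
    def test_condition_sets(self):
        m1, _ = generate_study_dataset("exp1", n_participants=2, seed=0)
        m2, _ = generate_study_dataset("exp2", n_participants=2, seed=0)
        assert m1["condition"].nunique() == 3
        assert m2["condition"].nunique() == 4

    def test_large_n_means_within_2pct(self):
        m, _ = generate_study_dataset("exp1", n_participants=450, seed=5)
        for cond, (mean, _) in ((c, EXP1_MOMENTS[c]["time"]) for c in EXP1_MOMENTS):
            emp = m.loc[m.condition == cond, "task_time_s"].mean()
            assert abs(emp - mean) / mean < 0.02, cond

    def test_same_seed_identical_tables(self):
        a = generate_study_dataset("exp1", n_participants=3, seed=8)
        b = generate_study_dataset("exp1", n_participants=3, seed=8)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_trial_counts_per_condition(self):
        m, _ = generate_study_dataset("exp2", n_participants=4, seed=1)
        counts = m.groupby(["participant", "condition"]).size()
        assert (counts == 5).all()

    def test_sus_scores_near_target(self):
        from tminav import sus_score

        _, q = generate_study_dataset("exp1", n_participants=300, seed=2)
        sus_cols = [f"sus{i}" for i in range(1, 11)]
        q["sus_score"] = [sus_score([int(v) for v in r]) for r in q[sus_cols].to_numpy()]
        for cond in EXP1_MOMENTS:
            target = EXP1_MOMENTS[cond]["sus"][0]
            assert q.loc[q.condition == cond, "sus_score"].mean() == pytest.approx(target, abs=2.5)

    def test_lognormal_distance_family_matches_moments(self):
        m, _ = generate_study_dataset("exp1", n_participants=500, seed=3, distance_family="lognormal")
        d = m.loc[m.condition == "circle_tmi", "euclidean_path_mm"]
        assert d.mean() == pytest.approx(16.2, rel=0.05)
        assert d.min() > 0

    def test_invalid_moments_rejected(self):
        bad = {c: dict(v) for c, v in EXP1_MOMENTS.items()}
        bad["circle_tmi"]["time"] = (-1.0, 2.0)
        with pytest.raises(ValueError, match="positive"):
            generate_study_dataset("exp1", n_participants=2, moments=bad, seed=0)


class TestTruncnormCalibration:
    def test_truncated_moments_match_targets(self):
        from scipy.stats import truncnorm

        for mean, std in [(10.9, 7.3), (6.4, 2.4), (24.0, 16.7)]:
            loc, scale = _truncnorm_params(mean, std, 0.0, np.inf)
            a = (0.0 - loc) / scale
            assert truncnorm.mean(a, np.inf, loc=loc, scale=scale) == pytest.approx(mean, abs=1e-6)
            assert truncnorm.std(a, np.inf, loc=loc, scale=scale) == pytest.approx(std, abs=1e-6)


class TestVolume:
    def test_entries_bright_background_dark(self):
        f = generate_spine_fixture()
        vol = generate_volume(f)
        for t in f.trajectories[:3]:
            i, j, k = np.round(vol.world_to_voxel(t.entry)).astype(int)
            assert vol.data[i, j, k] > 0
        assert vol.data[0, 0, 0] == 0.0

    def test_requested_shape(self):
        vol = generate_volume(generate_spine_fixture(), shape=(32, 40, 48), spacing=(3, 3, 3))
        assert vol.shape == (32, 40, 48)

    def test_deterministic(self):
        f = generate_spine_fixture()
        assert np.array_equal(generate_volume(f).data, generate_volume(f).data)

    def test_save_load_roundtrip(self, tmp_path):
        from tminav import VoxelVolume

        vol = generate_volume(generate_spine_fixture(), shape=(16, 16, 16))
        vol.save(tmp_path / "vol")
        back = VoxelVolume.load(tmp_path / "vol")
        np.testing.assert_allclose(back.data, vol.data)
        np.testing.assert_allclose(back.origin, vol.origin)


class TestSubstreams:
    def test_named_substreams_independent_and_reproducible(self):
        a1 = substream(7, "operator").normal(size=5)
        a2 = substream(7, "operator").normal(size=5)
        b = substream(7, "protocol").normal(size=5)
        assert np.array_equal(a1, a2)
        assert not np.array_equal(a1, b)
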