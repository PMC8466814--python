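"""Photomotor locomotion endpoints: speeds, bands, bursts, rotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zebraphys import (
    AcquisitionConfig,
    RotationParams,
    Trajectory,
    VelocityBands,
    banded_distance,
    count_bursts,
    count_rotations,
    locomotion_report,
    step_speeds,
)
from zebraphys.config import alternating_schedule
from zebraphys.errors import ConfigurationError, InsufficientDataError
from zebraphys.locomotion import band_of

from conftest import polygon_loop_trajectory


def _traj(x, y, frames=None, sid="t"):
    x = np.asarray(x, dtype=float)
    return Trajectory(sid, np.arange(len(x)) if frames is None else np.asarray(frames), x, np.asarray(y, dtype=float))


CFG = AcquisitionConfig(frame_rate=25.0, mm_per_pixel=0.25)


class TestStepSpeeds:
    def test_stationary_is_zero(self):
        t = _traj(np.zeros(10), np.zeros(10))
        assert np.all(step_speeds(t, CFG).speeds == 0.0)

    def test_straight_path_closed_form(self):
        # 1 mm per frame at 25 fps -> 25 mm/s
        t = _traj(np.arange(10.0), np.zeros(10))
        np.testing.assert_allclose(step_speeds(t, CFG).speeds, 25.0)

    def test_gap_scales_denominator(self):
        # frames 0,1,3,4: the 1->3 step spans 2 frame periods
        t = _traj([0.0, 1.0, 3.0, 4.0], [0.0] * 4, frames=[0, 1, 3, 4])
        s = step_speeds(t, CFG)
        np.testing.assert_allclose(s.speeds, [25.0, 25.0, 25.0])
        np.testing.assert_allclose(s.gaps, [1, 2, 1])

    def test_single_point_errors(self):
        with pytest.raises(InsufficientDataError):
            step_speeds(_traj([0.0], [0.0]), CFG)


class TestBandedDistance:
    def test_boundaries_fall_in_cruising(self):
        speeds = np.array([0.5, 20.0, 0.4999, 20.0001])
        assert list(band_of(speeds, VelocityBands())) == [
            "cruising", "cruising", "inactivity", "burst",
        ]

    def test_single_burst_step(self):
        t = _traj([0.0, 1.0], [0.0, 0.0])  # 25 mm/s > 20
        bd = banded_distance(step_speeds(t, CFG), VelocityBands())
        assert bd.loc[bd.band == "burst", "distance_mm"].sum() == pytest.approx(1.0)

    def test_hand_summed_fixture(self):
        # step lengths chosen to hit each band: speed = length * 25
        lengths = np.array([0.01, 0.01, 0.3, 0.3, 0.3, 0.9, 0.9, 0.01, 0.3, 0.9])
        x = np.concatenate([[0.0], np.cumsum(lengths)])
        bd = banded_distance(step_speeds(_traj(x, np.zeros(len(x))), CFG), VelocityBands())
        by_band = bd.groupby("band")["distance_mm"].sum()
        # by hand: inactivity 3 x 0.01, cruising 4 x 0.3, burst 3 x 0.9
        assert by_band["inactivity"] == pytest.approx(0.03)
        assert by_band["cruising"] == pytest.approx(1.2)
        assert by_band["burst"] == pytest.approx(2.7)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_band_distances_sum_to_total(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 200)
        x, y = np.cumsum(rng.normal(0, 0.5, n)), np.cumsum(rng.normal(0, 0.5, n))
        steps = step_speeds(_traj(x, y), CFG)
        bd = banded_distance(steps, VelocityBands())
        assert bd["distance_mm"].sum() == pytest.approx(steps.lengths.sum(), rel=1e-12)


class TestBursts:
    CFG_PHASED = AcquisitionConfig(
        frame_rate=25.0, mm_per_pixel=0.25, phase_schedule=[("light", 600.0)]
    )

    def test_sub_threshold_gives_no_events(self):
        n = int(600 * 25)
        x = np.cumsum(np.full(n + 1, 0.01))  # 0.25 mm/s << 5 mm/s threshold
        out = count_bursts(_traj(x, np.zeros(n + 1)), self.CFG_PHASED)
        assert out["events"].sum() == 0

    def test_three_runs_in_ten_minutes_is_point_three_per_minute(self):
        n = int(600 * 25)
        lengths = np.full(n, 0.01)
        for start in (1000, 5000, 9000):
            lengths[start : start + 10] = 0.5  # 12.5 mm/s >= 5 mm/s
        x = np.concatenate([[0.0], np.cumsum(lengths)])
        out = count_bursts(_traj(x, np.zeros(n + 1)), self.CFG_PHASED)
        assert out["events"].iloc[0] == 3
        assert out["rate_per_min"].iloc[0] == pytest.approx(0.3)

    def test_unbroken_run_is_one_event(self):
        n = int(600 * 25)
        x = np.cumsum(np.full(n + 1, 0.5))
        out = count_bursts(_traj(x, np.zeros(n + 1)), self.CFG_PHASED)
        assert out["events"].iloc[0] == 1

    def test_threshold_unit_equivalence(self):
        # px/s threshold with scale s behaves as the mm/s threshold 20*s
        n = 2000
        rng = np.random.default_rng(0)
        x = np.concatenate([[0.0], np.cumsum(rng.lognormal(-2, 1, n))])
        t = _traj(x, np.zeros(n + 1))
        cfg1 = AcquisitionConfig(frame_rate=25.0, mm_per_pixel=0.25, phase_schedule=[("light", 80.0)])
        cfg2 = AcquisitionConfig(frame_rate=25.0, mm_per_pixel=0.125, phase_schedule=[("light", 80.0)])
        out1 = count_bursts(t, cfg1, threshold_px_per_s=20.0)
        out2 = count_bursts(t, cfg2, threshold_px_per_s=40.0)
        assert out1["events"].tolist() == out2["events"].tolist()

    def test_missing_pixel_scale_errors(self):
        cfg = AcquisitionConfig(frame_rate=25.0, phase_schedule=[("light", 60.0)])
        with pytest.raises(ConfigurationError):
            count_bursts(_traj([0.0, 1.0], [0.0, 0.0]), cfg)


class TestRotations:
    def test_two_ccw_loops_of_four_mm(self):
        t = polygon_loop_trajectory(diameter=4.0, loops=2, direction="ccw")
        assert count_rotations(t) == (0, 2)

    def test_sub_two_mm_loop_abandoned(self):
        t = polygon_loop_trajectory(diameter=1.5, loops=1)
        assert count_rotations(t) == (0, 0)

    def test_straight_line_has_no_rotation(self):
        t = _traj(np.arange(20.0), np.zeros(20))
        assert count_rotations(t) == (0, 0)

    def test_cw_loop_counted_on_other_side(self):
        t = polygon_loop_trajectory(diameter=4.0, loops=3, direction="cw")
        assert count_rotations(t) == (3, 0)

    def test_invariant_under_translation_and_rotation(self):
        t = polygon_loop_trajectory(diameter=4.0, loops=2)
        th = 0.83
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        pts = t.points() @ R.T + np.array([12.3, -4.5])
        t2 = _traj(pts[:, 0], pts[:, 1])
        assert count_rotations(t2) == count_rotations(t)

    def test_reflection_swaps_cw_ccw(self):
        t = polygon_loop_trajectory(diameter=4.0, loops=2, direction="ccw")
        t_ref = _traj(t.x, -t.y)
        assert count_rotations(t_ref) == (2, 0)

    def test_back_angle_reversal_aborts_rotation(self):
        # 300 deg of CCW arc, a sharp reversal, then 200 deg CW: neither
        # direction accumulates a full consistent 360
        m = 36
        ang1 = 2 * np.pi / m * np.arange(31)          # 300 deg of turning
        headings = np.concatenate([ang1, ang1[-1] - np.pi / 2 - ang1[:21]])
        steps = 0.35 * np.exp(1j * headings)
        z = np.concatenate([[0], np.cumsum(steps)])
        assert count_rotations(_traj(z.real, z.imag)) == (0, 0)


class TestLocomotionReport:
    def test_dark_twice_light_distance(self, photomotor_config):
        from zebraphys.simulate import sim_trajectories

        trajs, _ = sim_trajectories(
            photomotor_config,
            n_subjects=2,
            speed_mean={"light": 1.5, "dark": 3.0},
            speed_sd={"light": 0.3, "dark": 0.6},
            seed=7,
        )
        rep = locomotion_report(trajs, photomotor_config)
        for sid in rep["subject_id"].unique():
            sub = rep[rep.subject_id == sid].set_index("endpoint_name")["value"]
            ratio = sub["distance_total_dark"] / sub["distance_total_light"]
            assert ratio == pytest.approx(2.0, abs=0.1)

    def test_identical_subjects_identical_rows(self, photomotor_config):
        n = int(240 * 25)
        rng = np.random.default_rng(3)
        x = np.cumsum(rng.normal(0, 0.1, n))
        y = np.cumsum(rng.normal(0, 0.1, n))
        t1 = Trajectory("a", np.arange(n), x, y)
        t2 = Trajectory("b", np.arange(n), x, y)
        rep = locomotion_report([t1, t2], photomotor_config)
        a = rep[rep.subject_id == "a"].set_index("endpoint_name")["value"]
        b = rep[rep.subject_id == "b"].set_index("endpoint_name")["value"]
        assert (a == b).all()

    def test_single_phase_schedule(self):
        cfg = AcquisitionConfig(frame_rate=25.0, mm_per_pixel=0.25, phase_schedule=[("dark", 60.0)])
        n = int(60 * 25)
        t = Trajectory("s", np.arange(n), np.cumsum(np.full(n, 0.05)), np.zeros(n))
        rep = locomotion_report([t], cfg)
        assert set(rep["endpoint_name"].str.rsplit("_", n=1).str[-1]) == {"dark"}

    def test_band_sum_matches_total_endpoint(self, photomotor_config):
        from zebraphys.simulate import sim_trajectories

        trajs, _ = sim_trajectories(photomotor_config, n_subjects=1, seed=1)
        rep = locomotion_report(trajs, photomotor_config).set_index("endpoint_name")["value"]
        for phase in ("light", "dark"):
            parts = sum(
                rep[f"distance_{band}_{phase}"] for band in ("inactivity", "cruising", "burst")
            )
            assert parts == pytest.approx(rep[f"distance_total_{phase}"], rel=1e-12)
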