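"""Trajectory analytics: registration, direction series, seeking, scores."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import sawtooth

import soundnav as sn
from soundnav.analytics import _detrend
from soundnav.errors import (
    ConfigError,
    DirectionError,
    GimbalError,
    IncompleteTrialError,
    RegistrationError,
)
from soundnav.transforms import Pose, yaw_quaternion, quat_multiply


def _straight_log(n=200, speed=0.5, dt=1 / 60, yaw=0.0, fiducial=None):
    """Course-frame walk along +X at constant speed."""
    samples = [
        sn.PoseSample(i * dt, [-0.5 + speed * i * dt, 0.0, 1.4], yaw_quaternion(yaw))
        for i in range(n)
    ]
    return sn.SessionLog(samples=samples, fiducial=fiducial or Pose(), trial_id="straight")


class TestRegistration:
    def test_log_in_target_frame_gives_identity(self):
        log = _straight_log()
        traj = sn.register_session(log, Pose())
        assert np.allclose(traj.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(traj.translation, 0.0, atol=1e-12)

    def test_three_random_session_frames_align(self, empty_course):
        """Fig-8-style check: one truth path under three random session
        frames registers to < 1e-6 m pairwise discrepancy."""
        b = sn.BehaviorParams(seek_amplitude=0.2, seek_frequency=0.25)
        regs = [
            sn.register_session(
                sn.simulate_trial(empty_course, b, arbitrary_frame_seed=s)[0],
                empty_course.fiducial_pose,
            ).positions()
            for s in (101, 202, 303)
        ]
        for other in regs[1:]:
            assert np.abs(regs[0] - other).max() < 1e-6

    def test_quarter_turn_session_frame_restores_travel_along_x(self):
        theta = math.pi / 2
        R = np.array(
            [[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]
        )
        truth = _straight_log()
        rotated = sn.SessionLog(
            samples=[
                sn.PoseSample(
                    s.timestamp, R @ s.position,
                    quat_multiply(yaw_quaternion(theta), s.orientation),
                )
                for s in truth.samples
            ],
            fiducial=Pose(orientation=yaw_quaternion(theta)),
            trial_id="rotated",
        )
        traj = sn.register_session(rotated, Pose())
        d = np.diff(traj.positions(), axis=0)
        assert np.allclose(d[:, 1:], 0.0, atol=1e-9)
        assert np.all(d[:, 0] > 0)

    def test_fiducial_maps_to_target(self, study_layout):
        b = replace(sn.BEHAVIOR_PRESETS["assisted"], seed=2)
        log, _ = sn.simulate_trial(study_layout, b, arbitrary_frame_seed=5)
        traj = sn.register_session(log, study_layout.fiducial_pose)
        mapped = traj.rotation @ log.fiducial.position + traj.translation
        assert np.allclose(mapped, study_layout.fiducial_pose.position, atol=1e-6)
        mapped_R = traj.rotation @ log.fiducial.rotation().as_matrix()
        target_R = study_layout.fiducial_pose.rotation().as_matrix()
        assert np.allclose(mapped_R, target_R, atol=1e-6)

    def test_general_tilted_fiducial_alignment(self, rng):
        """Sequential X-then-Y alignment handles fiducials of arbitrary
        orientation, not just planar rotations."""
        from scipy.spatial.transform import Rotation

        for _ in range(20):
            q = Rotation.random(random_state=int(rng.integers(2**31))).as_quat()
            fid = Pose(rng.normal(size=3), np.roll(q, 1))
            log = _straight_log(fiducial=fid)
            target = Pose(
                rng.normal(size=3),
                np.roll(Rotation.random(random_state=int(rng.integers(2**31))).as_quat(), 1),
            )
            traj = sn.register_session(log, target)
            mapped = traj.rotation @ fid.position + traj.translation
            assert np.allclose(mapped, target.position, atol=1e-9)
            assert np.allclose(
                traj.rotation @ fid.rotation().as_matrix(),
                target.rotation().as_matrix(),
                atol=1e-9,
            )


class TestTravelDirection:
    def test_straight_x_walk_is_zero(self):
        pos = np.column_stack([np.linspace(0, 5, 100), np.zeros(100), np.zeros(100)])
        ts = np.arange(100) / 60
        assert np.allclose(sn.travel_direction(pos, ts), 0.0)

    def test_straight_y_walk_is_half_pi(self):
        pos = np.column_stack([np.zeros(100), np.linspace(0, 5, 100), np.zeros(100)])
        ts = np.arange(100) / 60
        assert np.allclose(sn.travel_direction(pos, ts), math.pi / 2)

    def test_l_shaped_path_steps_down_half_pi(self):
        # +X leg then -Y leg: direction drops from 0 to -pi/2 at the turn
        leg1 = np.column_stack([np.linspace(0, 2, 50), np.zeros(50)])
        leg2 = np.column_stack([np.full(50, 2.0), np.linspace(-0.04, -2, 50)])
        pos = np.column_stack([np.vstack([leg1, leg2]), np.zeros(100)])
        ts = np.arange(100) / 60
        ang = sn.travel_direction(pos, ts, smoothing_window=0.0)
        assert ang[0] == pytest.approx(0.0)
        assert ang[-1] == pytest.approx(-math.pi / 2)
        assert ang.min() >= -math.pi / 2 - 1e-9

    def test_stationary_steps_inherit_last_angle(self):
        pos = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 0, 0], [1, 0, 0], [1, 1, 0]], dtype=float
        )
        ts = np.arange(5.0)
        ang = sn.travel_direction(pos, ts, smoothing_window=0.0, stationary_epsilon=1e-3)
        assert ang[0] == pytest.approx(0.0)
        assert ang[1] == pytest.approx(0.0)  # inherited
        assert ang[2] == pytest.approx(0.0)  # inherited
        assert ang[3] == pytest.approx(math.pi / 2)

    def test_all_stationary_raises(self):
        pos = np.zeros((10, 3))
        with pytest.raises(DirectionError):
            sn.travel_direction(pos, np.arange(10.0))


class TestYawAngle:
    def test_identity_and_quarter_turn(self):
        assert sn.yaw_angle([1, 0, 0, 0]) == pytest.approx(0.0)
        assert sn.yaw_angle(yaw_quaternion(math.pi / 2)) == pytest.approx(math.pi / 2)

    def test_matches_rotation_matrix_oracle(self, rng):
        """Random quaternions: heading equals atan2 of the matrix-rotated
        forward axis, to 1e-9."""
        from scipy.spatial.transform import Rotation

        q = rng.normal(size=(2000, 4))
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        for qi in q:
            try:
                ours = sn.yaw_angle(qi)
            except GimbalError:
                continue
            w, x, y, z = qi
            fwd = Rotation.from_quat([x, y, z, w]).as_matrix() @ [1.0, 0, 0]
            assert ours == pytest.approx(math.atan2(fwd[1], fwd[0]), abs=1e-9)

    def test_vertical_forward_axis_raises(self):
        # -90 deg about Y points the forward axis straight up
        q = [math.cos(math.pi / 4), 0.0, -math.sin(math.pi / 4), 0.0]
        with pytest.raises(GimbalError):
            sn.yaw_angle(q)

    def test_series_is_unwrapped(self):
        angles = np.linspace(0, 4 * math.pi, 300)
        quats = np.array([yaw_quaternion(a) for a in angles])
        series = sn.yaw_angle(quats)
        assert np.all(np.abs(np.diff(series)) < 1.0)
        assert series[-1] == pytest.approx(4 * math.pi)


def _brute_force_seeking(detrended, fraction=0.075):
    """Independent oracle: loop-based extrema + naive topographic prominence."""
    d = np.asarray(detrended, float)
    scale = np.abs(d).max()
    if scale == 0:
        return 0.0
    total = 0.0
    for series in (d, -d):
        n = len(series)
        for i in range(1, n - 1):
            if not (series[i] > series[i - 1] and series[i] >= series[i + 1]):
                continue
            if series[i] <= 0:
                continue
            # prominence: lowest descent before reaching a higher bar, each side
            key = []
            for rng_ in (range(i - 1, -1, -1), range(i + 1, n)):
                low = series[i]
                for j in rng_:
                    if series[j] > series[i]:
                        break
                    low = min(low, series[j])
                key.append(low)
            prominence = series[i] - max(key)
            if prominence > fraction * scale:
                total += abs(d[i])
    return total


class TestSeeking:
    def _triangle(self, amplitude, cycles, n=600, phase=math.pi / 2):
        t = np.linspace(0, cycles, n, endpoint=False)
        return amplitude * sawtooth(2 * np.pi * t + phase, 0.5)

    def test_matches_brute_force_oracle(self):
        wave = self._triangle(0.5, 3)
        dev = sn.DeviationSeries.from_deviation(wave)
        assert sn.seeking_score(dev) == pytest.approx(
            _brute_force_seeking(dev.detrended), abs=1e-9
        )

    @pytest.mark.parametrize("A,K", [(0.5, 3), (0.3, 5), (0.5, 3.5)])
    def test_triangle_scores_two_k_amplitude(self, A, K):
        # K sweep cycles, amplitude A: one left and one right peak per cycle,
        # each contributing ~A after the detrend (finite-window detrending
        # shifts peak values by a few percent, inside the 10% band)
        dev = sn.DeviationSeries.from_deviation(self._triangle(A, K))
        assert sn.seeking_score(dev) == pytest.approx(2 * K * A, rel=0.10)

    def test_zero_series_scores_zero(self):
        dev = sn.DeviationSeries.from_deviation(np.zeros(100))
        assert sn.seeking_score(dev) == 0.0

    def test_linear_drift_removed_exactly(self):
        wave = self._triangle(0.5, 3)
        drift = np.linspace(0.0, 0.2, len(wave))
        a = sn.seeking_score(sn.DeviationSeries.from_deviation(wave))
        b = sn.seeking_score(sn.DeviationSeries.from_deviation(wave + drift))
        assert b == pytest.approx(a, abs=1e-9)

    def test_small_jitter_rejected_by_prominence_filter(self, rng):
        wave = self._triangle(0.5, 3) + 0.01 * rng.normal(size=600)
        dev = sn.DeviationSeries.from_deviation(wave)
        assert sn.seeking_score(dev) == pytest.approx(2 * 3 * 0.5, rel=0.15)

    def test_detrending_is_idempotent(self, rng):
        y = rng.normal(size=500).cumsum()
        once = _detrend(y)
        assert np.abs(_detrend(once) - once).max() < 1e-12


class TestElapsedTime:
    def _walk(self, xs, dt=1 / 60):
        return [
            sn.PoseSample(i * dt, [x, 0.0, 1.4], [1, 0, 0, 0]) for i, x in enumerate(xs)
        ]

    def test_constant_speed_kinematics(self):
        xs = -0.5 + 0.5 * np.arange(2000) / 60  # 0.5 m/s from x = -0.5
        elapsed = sn.elapsed_time(self._walk(xs), 0.0, 12.0)
        assert elapsed == pytest.approx(24.0, abs=1 / 60 + 1e-9)

    def test_stopping_short_is_incomplete(self):
        xs = np.linspace(-0.5, 11.0, 800)
        with pytest.raises(IncompleteTrialError) as err:
            sn.elapsed_time(self._walk(xs), 0.0, 12.0)
        assert err.value.time_cap == 180.0

    def test_backtracking_counts_first_crossing_only(self):
        # crosses 12 m, backtracks below it, then finishes again
        xs = np.concatenate(
            [np.linspace(-0.5, 12.3, 500), np.linspace(12.3, 11.0, 100),
             np.linspace(11.0, 12.5, 100)]
        )
        samples = self._walk(xs)
        elapsed = sn.elapsed_time(samples, 0.0, 12.0)
        first_cross = next(s.timestamp for s in samples if s.position[0] > 12.0)
        first_start = next(s.timestamp for s in samples if s.position[0] > 0.0)
        assert elapsed == pytest.approx(first_cross - first_start, abs=1e-12)


class TestScores:
    def test_spi_worked_examples(self):
        assert sn.spi(50.0, 0) == pytest.approx(0.02, abs=1e-15)
        assert sn.spi(67.0, 2) == pytest.approx(1.0 / 201.0, abs=1e-15)

    def test_spi_decreases_with_collisions(self):
        vals = [sn.spi(40.0, c) for c in range(6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    @given(
        st.floats(1.0, 500.0),
        st.integers(0, 30),
    )
    def test_spi_exactness_property(self, elapsed, collisions):
        assert sn.spi(elapsed, collisions) * elapsed * (collisions + 1) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_spi_invalid_elapsed(self):
        with pytest.raises(ConfigError):
            sn.spi(0.0, 1)

    def test_normalize_scores_examples(self):
        assert np.allclose(sn.normalize_scores([0.02, 0.01]), [1.0, 0.5])
        assert np.allclose(sn.normalize_scores([0.37]), [1.0])

    @given(st.lists(st.floats(0.0, 10.0), min_size=1, max_size=20).filter(lambda v: max(v) > 0))
    def test_normalize_scores_properties(self, values):
        out = sn.normalize_scores(values)
        assert out.max() == 1.0
        order = np.argsort(values, kind="stable")
        assert np.array_equal(np.argsort(out, kind="stable"), order)
        # permutation equivariance
        perm = np.random.default_rng(0).permutation(len(values))
        assert np.allclose(np.asarray(out)[perm], sn.normalize_scores(np.asarray(values)[perm]))

    def test_normalize_all_zero_rejected(self):
        with pytest.raises(ConfigError):
            sn.normalize_scores([0.0, 0.0])

    def test_adrev_degenerate_group(self):
        raw, scaled = sn.adrev(50.0, 2, [(50.0, 2)])
        assert raw == pytest.approx(0.04)
        assert scaled == 1.0

    def test_adrev_sprinter_hypothetical(self):
        # fast + all collisions vs slow + none: the sprinter scores higher raw
        group = [(10.0, 5), (100.0, 0)]
        raw_s, scaled_s = sn.adrev(10.0, 5, group)
        raw_c, scaled_c = sn.adrev(100.0, 0, group)
        assert raw_s == pytest.approx(0.5) and raw_c == pytest.approx(0.0)
        assert scaled_s == pytest.approx(8.0) and scaled_c == pytest.approx(1.0)
        # orientation flag flips the scale
        assert sn.adrev(10.0, 5, group, reverse=True)[1] == pytest.approx(1.0)

    def test_adrev_bounds_random_groups(self, rng):
        for _ in range(20):
            group = [
                (float(rng.uniform(20, 150)), int(rng.integers(0, 8)))
                for _ in range(6)
            ]
            for te, ce in group:
                _, scaled = sn.adrev(te, ce, group)
                assert 1.0 - 1e-12 <= scaled <= 8.0 + 1e-12

    def test_adrev_requires_membership(self):
        with pytest.raises(ConfigError):
            sn.adrev(33.0, 1, [(10.0, 5)])

    def test_survey_normalization(self):
        assert sn.normalize_survey([6] * 6) == pytest.approx(1.00)
        assert sn.normalize_survey([1] * 6) == pytest.approx(0.0)
        assert sn.normalize_survey([1, 6]) == pytest.approx(0.5)
        with pytest.raises(ConfigError):
            sn.normalize_survey([0, 6])
        with pytest.raises(ConfigError):
            sn.normalize_survey([7])


class TestTrialReport:
    def test_clean_straight_run(self, empty_course):
        b = sn.BehaviorParams(forward_speed=0.4, seek_amplitude=0.0)
        log, events = sn.simulate_trial(empty_course, b, arbitrary_frame_seed=3)
        m = sn.trial_report(log, empty_course, events=events)
        assert m.collisions == 0
        assert m.seeking == pytest.approx(0.0, abs=1e-9)
        assert m.spi_raw == pytest.approx(1.0 / m.elapsed_time)
        assert not m.incomplete

    def test_metrics_invariant_to_session_frame(self, study_layout):
        """Identical truth trajectory under two different arbitrary session
        frames yields identical metrics after registration."""
        b = replace(sn.BEHAVIOR_PRESETS["assisted"], seed=5)
        m1 = sn.trial_report(
            sn.simulate_trial(study_layout, b, arbitrary_frame_seed=21)[0], study_layout
        )
        m2 = sn.trial_report(
            sn.simulate_trial(study_layout, b, arbitrary_frame_seed=99)[0], study_layout
        )
        assert m1.elapsed_time == pytest.approx(m2.elapsed_time, abs=1e-9)
        assert m1.collisions == m2.collisions
        assert m1.seeking == pytest.approx(m2.seeking, abs=1e-7)
        assert m1.spi_raw == pytest.approx(m2.spi_raw, abs=1e-12)

    def test_mode_flag_does_not_change_metrics(self, study_layout):
        b = replace(sn.BEHAVIOR_PRESETS["assisted"], seed=5)
        log_a, _ = sn.simulate_trial(study_layout, b, arbitrary_frame_seed=21, mode="active")
        log_p, _ = sn.simulate_trial(study_layout, b, arbitrary_frame_seed=21, mode="passive")
        m_a = sn.trial_report(log_a, study_layout)
        m_p = sn.trial_report(log_p, study_layout)
        assert m_a.elapsed_time == m_p.elapsed_time
        assert m_a.seeking == m_p.seeking

    def test_regression_against_frozen_seeded_values(self, study_layout):
        """End-to-end metrics of one fixed seeded trial, frozen once; elapsed
        time re-derived independently from the crossing timestamps."""
        b = replace(sn.BEHAVIOR_PRESETS["assisted"], seed=7)
        log, events = sn.simulate_trial(study_layout, b, arbitrary_frame_seed=17)
        m = sn.trial_report(log, study_layout, events=events)
        assert m.elapsed_time == pytest.approx(71.41666666666666, abs=1e-9)
        assert m.collisions == 0
        assert m.seeking == pytest.approx(19.493190877545764, rel=1e-9)
        assert m.spi_raw == pytest.approx(0.01400233372228705, rel=1e-12)
        # independent elapsed-time oracle on the registered trajectory
        traj = sn.register_session(log, study_layout.fiducial_pose)
        x, t = traj.positions()[:, 0], traj.timestamps()
        ref = t[np.argmax(x > 12.0)] - t[np.argmax(x > 0.0)]
        assert m.elapsed_time == pytest.approx(ref, abs=1e-12)

    def test_incomplete_trial_flagged_with_cap(self, empty_course):
        # walk that stops before the finish: truncate a simulated log
        b = sn.BehaviorParams(forward_speed=0.4)
        log, _ = sn.simulate_trial(empty_course, b, arbitrary_frame_seed=3)
        short = sn.SessionLog(
            samples=log.samples[: len(log.samples) // 2],
            fiducial=log.fiducial,
            mode=log.mode,
            trial_id="short",
        )
        m = sn.trial_report(short, empty_course)
        assert m.incomplete
        assert m.elapsed_time == 180.0

    def test_group_scores_populated(self, empty_course):
        b = sn.BehaviorParams(forward_speed=0.4)
        log, events = sn.simulate_trial(empty_course, b, arbitrary_frame_seed=3)
        m0 = sn.trial_report(log, empty_course, events=events)
        group = [(m0.elapsed_time, m0.collisions), (m0.elapsed_time * 2, 3)]
        m = sn.trial_report(log, empty_course, events=events, group=group)
        assert m.spi_normalized == pytest.approx(1.0)
        assert 1.0 <= m.adrev_scaled <= 8.0


class TestAggregate:
    def test_report_has_slopes_per_mode(self, empty_course):
        ms = []
        for k in range(4):
            b = sn.BehaviorParams(forward_speed=0.3 + 0.02 * k)
            log, ev = sn.simulate_trial(
                empty_course, b, arbitrary_frame_seed=k,
                mode="active" if k % 2 else "passive", trial_id=f"t{k}",
            )
            ms.append(sn.trial_report(log, empty_course, events=ev))
        per_trial, agg = sn.aggregate_report(ms)
        assert len(per_trial) == 4
        assert per_trial["spi_normalized"].max() == 1.0
        assert {"active", "passive"} == set(agg["mode"])
        assert "slope_elapsed_time_s" in agg.columns
        assert "slope_spi_normalized" in agg.columns
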