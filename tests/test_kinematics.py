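"""IMU kinematics: camber correction, velocities, timing rules, trajectory."""

import math

import numpy as np
import pytest

from wheelperf import (
    camber_correct,
    dead_reckon,
    detect_course_end,
    detect_sprint_end,
    detect_start,
    field_outcomes,
    process_recording,
    to_linear,
)
from wheelperf.errors import (
    AlignmentError,
    IncompleteTestError,
    InvalidInputError,
    InvalidRateError,
    MissingSensorError,
    NoMotionError,
)
from wheelperf.kinematics import ImuRecording, filter_imu, rotational_velocity


class TestCamberCorrect:
    def test_direct_evaluation(self):
        # 300 + sin(18 deg) * 90 = 327.81 deg/s
        out = camber_correct(np.array([300.0]), np.array([90.0]), 18.0)
        assert out[0] == pytest.approx(300.0 + math.sin(math.radians(18.0)) * 90.0, abs=1e-9)
        assert round(float(out[0]), 2) == 327.81

    def test_zero_camber_identity(self):
        gy = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(camber_correct(gy, np.array([9.0, 9.0, 9.0]), 0.0), gy)

    def test_zero_frame_yaw_identity(self):
        gy = np.array([10.0, 20.0])
        assert np.array_equal(camber_correct(gy, np.zeros(2), 33.0), gy)

    def test_length_mismatch(self):
        with pytest.raises(AlignmentError):
            camber_correct(np.zeros(3), np.zeros(4), 10.0)


class TestToLinear:
    @pytest.mark.parametrize(
        "wc,v_ang,expected",
        [(2.0, 360.0, 2.0), (2.073, 180.0, 1.0365), (1.5, 0.0, 0.0)],
    )
    def test_direct_evaluation(self, wc, v_ang, expected):
        assert to_linear(np.array([v_ang]), wc)[0] == pytest.approx(expected, abs=1e-9)


class TestFilterImu:
    def test_dc_gain_after_transient(self):
        x = np.full(2000, 5.0)
        y = filter_imu(x, 200.0)
        assert np.allclose(y[500:], 5.0, atol=1e-6)

    def test_cutoff_gain_is_minus_3db(self):
        t = np.arange(0, 20, 0.005)
        y = filter_imu(np.sin(2 * np.pi * 10.0 * t), 200.0)
        amp = np.max(np.abs(y[len(y) // 2 :]))
        assert amp == pytest.approx(1.0 / math.sqrt(2.0), rel=0.02)

    def test_zero_in_zero_out(self):
        assert np.all(filter_imu(np.zeros(100), 200.0) == 0.0)

    def test_low_rate_rejected(self):
        with pytest.raises(InvalidRateError):
            filter_imu(np.zeros(100), 20.0)


class TestStartEndRules:
    def test_ramp_crossing(self):
        # v = 0.05 t at 100 Hz: v > 0.1 first at one sample past t = 2 s
        t = np.arange(0, 5, 0.01)
        assert detect_start(0.05 * t) == 201

    def test_already_moving_is_rejected(self):
        with pytest.raises(InvalidInputError):
            detect_start(np.full(100, 0.2))

    def test_no_motion(self):
        with pytest.raises(NoMotionError):
            detect_start(np.zeros(100))

    def test_sprint_end_constant_velocity(self):
        t = np.arange(0, 8, 0.01)
        d = 2.0 * t
        assert t[detect_sprint_end(d, d)] == pytest.approx(5.0, abs=0.011)

    def test_sprint_end_averages_both_wheels(self):
        t = np.arange(0, 8, 0.01)
        idx = detect_sprint_end(4.0 * t, np.zeros_like(t))
        assert 4.0 * t[idx] == pytest.approx(20.0, abs=0.05)

    def test_sprint_end_incomplete(self):
        d = np.linspace(0, 9.9, 500)
        with pytest.raises(IncompleteTestError):
            detect_sprint_end(d, d)


class TestDeadReckoning:
    def test_straight_line(self):
        n = 2001
        x, y = dead_reckon(np.ones(n), np.zeros(n), 200.0)
        assert x[-1] == pytest.approx(10.0, abs=1e-9)
        assert abs(y[-1]) < 1e-12

    def test_full_circle_closes(self):
        fs = 200.0
        n = int(10 * fs) + 1
        x, y = dead_reckon(np.ones(n), np.full(n, 36.0), fs)
        assert math.hypot(x[-1], y[-1]) < 1e-3

    def test_zero_input_stays_at_origin(self):
        x, y = dead_reckon(np.zeros(100), np.zeros(100), 200.0)
        assert np.all(x == 0.0) and np.all(y == 0.0)


class TestCourseEnd:
    def test_out_and_back(self):
        fs = 100.0
        t = np.arange(0, 11, 1 / fs)
        x = np.where(t < 5, t, 10 - t)  # out 5 m, back through the start
        y = np.zeros_like(t)
        idx = detect_course_end(x, y, t, start_idx=0, heading0=0.0)
        assert t[idx] == pytest.approx(10.0, abs=0.02)

    def test_monotone_path_incomplete(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(IncompleteTestError):
            detect_course_end(t.copy(), np.zeros_like(t), t, start_idx=0, heading0=0.0)

    def test_detected_duration_matches_truth(self, illinois_noiseless):
        params, truth, imu = illinois_noiseless
        kin = process_recording(imu, "illinois", filter_mode="none")
        detected = kin.t[kin.end_idx] - kin.t[kin.start_idx]
        assert detected == pytest.approx(truth.duration, abs=2 / params.imu_sample_rate)


class TestPipeline:
    def test_noiseless_roundtrip(self, sprint_noiseless):
        params, truth, imu, _ = sprint_noiseless
        kin = process_recording(imu, "sprint", filter_mode="none")
        v_true = np.interp(imu.t, truth.t, truth.v_lin)
        w_true = np.interp(imu.t, truth.t, truth.v_rot)
        assert np.max(np.abs(kin.v_lin - v_true)) < 0.01
        assert np.max(np.abs(kin.v_rot - w_true)) < 0.5

    def test_straight_sprint_has_no_yaw(self, sprint_noisy):
        _, _, imu, _ = sprint_noisy
        kin = process_recording(imu, "sprint")
        assert np.max(np.abs(kin.v_rot)) < 5.0

    def test_spider_peak_yaw_matches_cap(self, spider_noiseless):
        params, _, imu = spider_noiseless
        kin = process_recording(imu, "spider", filter_mode="none")
        out = field_outcomes(kin, "spider")
        assert out.v_peak_rot == pytest.approx(params.course.yaw_rate_max, rel=0.02)

    def test_missing_frame_sensor(self, sprint_noiseless):
        _, _, imu, _ = sprint_noiseless
        broken = ImuRecording(
            t=imu.t, gyro={k: v for k, v in imu.gyro.items() if k != "frame"},
            chest_pitch=imu.chest_pitch,
            wheel_circumference=imu.wheel_circumference, camber=imu.camber,
        )
        with pytest.raises(MissingSensorError):
            rotational_velocity(broken)

    def test_mirrored_course_same_peak_yaw_magnitude(self):
        from wheelperf import SimulationParams, simulate_course
        from wheelperf.params import CourseSpec, spider_course

        base = spider_course()
        mirrored = CourseSpec(
            kind="spider",
            waypoints=tuple((x, -y) for x, y in base.waypoints),
        )
        a, _ = simulate_course(SimulationParams(course=base, gyro_noise_sd=0.0))
        b, _ = simulate_course(SimulationParams(course=mirrored, gyro_noise_sd=0.0))
        assert np.max(np.abs(a.v_rot)) == pytest.approx(np.max(np.abs(b.v_rot)), rel=1e-9)


class TestFieldOutcomes:
    def test_sprint_has_no_rotational_peak(self, sprint_noiseless):
        _, truth, imu, _ = sprint_noiseless
        kin = process_recording(imu, "sprint", filter_mode="none")
        out = field_outcomes(kin, "sprint")
        assert out.v_peak_rot is None
        assert out.v_peak_lin == pytest.approx(
            np.max(truth.v_lin[truth.start_idx : truth.end_idx + 1]), rel=0.01
        )

    def test_illinois_has_both_peaks(self, illinois_noiseless):
        _, _, imu = illinois_noiseless
        kin = process_recording(imu, "illinois", filter_mode="none")
        out = field_outcomes(kin, "illinois")
        assert out.v_peak_lin is not None and out.v_peak_rot is not None
        assert out.duration > 0

    def test_peak_at_least_mean_velocity(self, sprint_noisy):
        _, _, imu, _ = sprint_noisy
        kin = process_recording(imu, "sprint")
        out = field_outcomes(kin, "sprint")
        window = kin.v_lin[kin.start_idx : kin.end_idx + 1]
        assert out.v_peak_lin >= np.mean(window)
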