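"""Simulator: dynamics oracles, energy bookkeeping, rendering, cohort."""

import math

import numpy as np
import pytest

from wheelperf import (
    SimulationParams,
    render_ergometer,
    simulate_coastdown_pair,
    simulate_cohort,
    simulate_course,
    simulate_linear_sprint,
)
from wheelperf.errors import (
    DegenerateTrialError,
    InvalidCourseError,
    InvalidParameterError,
)
from wheelperf.params import G, CourseSpec, coastdown_course, spider_course, sprint_course
from wheelperf.simulate import _clamped_cumulative, front_load_fraction


class TestStraightDynamics:
    def test_zero_push_force_keeps_chair_at_rest(self):
        params = SimulationParams(push_peak_force=0.0, gyro_noise_sd=0.0)
        truth, imu, erg = simulate_linear_sprint(params)
        assert np.all(truth.v_lin == 0.0)
        assert np.all(truth.x == 0.0)
        for sensor in ("left_wheel", "right_wheel", "frame"):
            assert np.all(imu.gyro[sensor] == 0.0)
        assert truth.start_idx is None and truth.mean_power is None

    def test_uniform_acceleration_closed_form(self):
        # constant net 50 N on 100 kg, frictionless: v(4 s) = 2, x(4 s) = 4
        fs = 1000.0
        n = int(4 * fs)
        g_end = np.full(n + 1, 50.0 / 100.0)
        dv = np.full(n, 0.5 / fs)
        v = _clamped_cumulative(dv, g_end)
        t = np.arange(n + 1) / fs
        x = np.trapezoid(v, t)
        assert v[-1] == pytest.approx(2.0, abs=1e-12)
        assert x == pytest.approx(4.0, abs=1e-9)

    def test_energy_bookkeeping(self, sprint_noiseless):
        params, truth, _, _ = sprint_noiseless
        work_in = np.trapezoid(truth.F_push * truth.v_lin, truth.t)
        losses = np.trapezoid(truth.F_roll * truth.v_lin, truth.t)
        dke = 0.5 * params.m_total * truth.v_lin[-1] ** 2
        assert work_in == pytest.approx(losses + dke, rel=1e-3)

    def test_identical_seed_is_bit_identical(self):
        a = simulate_linear_sprint(SimulationParams(seed=5))
        b = simulate_linear_sprint(SimulationParams(seed=5))
        assert np.array_equal(a[0].v_lin, b[0].v_lin)
        for sensor in a[1].gyro:
            assert np.array_equal(a[1].gyro[sensor], b[1].gyro[sensor])
        assert np.array_equal(a[2].torque_left, b[2].torque_left)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            SimulationParams(body_mass=-1.0)
        with pytest.raises(InvalidParameterError):
            SimulationParams(imu_sample_rate=0.0)
        with pytest.raises(InvalidParameterError):
            SimulationParams(push_duration=1.0, cycle_period=0.5)


class TestCoastdown:
    def test_frictionless_coast_holds_velocity(self):
        params = SimulationParams(
            mu_front=0.0, mu_rear=0.0, gyro_noise_sd=0.0, course=coastdown_course()
        )
        truth, _ = simulate_coastdown_pair(params)[0]
        a, b = truth.coast_bounds
        coast = truth.v_lin[a:b]
        assert np.ptp(coast) < 1e-9

    def test_coast_deceleration_matches_mu_m_g(self):
        # mu = 0.012 on both axles: decel = 0.012 * 9.81 independent of posture
        params = SimulationParams(
            body_mass=88.0, chair_mass=12.0, mu_front=0.012, mu_rear=0.012,
            gyro_noise_sd=0.0, course=coastdown_course(),
        )
        truth, _ = simulate_coastdown_pair(params)[0]
        a, b = truth.coast_bounds
        slope = np.polyfit(truth.t[a:b], truth.v_lin[a:b], 1)[0]
        assert -slope == pytest.approx(0.012 * G, rel=1e-3)

    def test_forward_lean_decelerates_faster(self, coastdown_noiseless):
        # mu_front > mu_rear: more front load -> larger deceleration
        _, trials = coastdown_noiseless
        decels = []
        for truth, _ in trials:
            a, b = truth.coast_bounds
            decels.append(-np.polyfit(truth.t[a:b], truth.v_lin[a:b], 1)[0])
        assert decels[2] > decels[0]
        assert decels[3] > decels[1]

    def test_too_weak_pushes_are_degenerate(self):
        params = SimulationParams(
            push_peak_force=10.0, gyro_noise_sd=0.0, course=coastdown_course()
        )
        with pytest.raises(DegenerateTrialError):
            simulate_coastdown_pair(params)


class TestCourses:
    def test_out_and_back_returns_to_start(self):
        course = CourseSpec(kind="illinois", waypoints=((0, 0), (5, 0), (0, 0)))
        truth, _ = simulate_course(SimulationParams(course=course, gyro_noise_sd=0.0))
        assert abs(truth.x[-1]) < 0.01 and abs(truth.y[-1]) < 0.01

    def test_yaw_rate_cap_is_attained(self, spider_noiseless):
        _, truth, _ = spider_noiseless
        cap = spider_course().yaw_rate_max
        assert np.max(np.abs(truth.v_rot)) == pytest.approx(cap, rel=1e-12)

    @pytest.mark.parametrize("factory", [spider_course, lambda: CourseSpec(
        kind="illinois", waypoints=((0, 0), (10, 0), (10, 3.3), (-0.5, 3.3)))])
    def test_speed_integral_equals_path_length(self, factory):
        truth, _ = simulate_course(SimulationParams(course=factory(), gyro_noise_sd=0.0))
        path = float(np.sum(np.hypot(np.diff(truth.x), np.diff(truth.y))))
        integral = float(np.trapezoid(truth.v_lin, truth.t))
        assert path == pytest.approx(integral, rel=0.005)

    def test_single_waypoint_course_rejected(self):
        course = CourseSpec(kind="spider", waypoints=((0.0, 0.0),))
        with pytest.raises(InvalidCourseError):
            simulate_course(SimulationParams(course=course))

    def test_velocity_never_negative(self, illinois_noiseless):
        _, truth, _ = illinois_noiseless
        assert np.all(truth.v_lin >= 0.0)


class TestRendering:
    def test_zero_camber_wheel_gyro_is_scaled_velocity(self, sprint_noiseless):
        params, truth, _, _ = sprint_noiseless
        from wheelperf.simulate import render_imu

        flat = SimulationParams(camber=0.0, gyro_noise_sd=0.0)
        imu = render_imu(truth, flat)
        v = np.interp(imu.t, truth.t, truth.v_lin)
        expected = 360.0 / flat.wheel_circumference * v
        assert np.allclose(imu.gyro["left_wheel"][:, 1], expected, atol=1e-9)

    def test_camber_coupling_subtracts_frame_yaw(self):
        # true v_ang 300 deg/s with 90 deg/s yaw at 18 deg camber:
        # wheel gyro reads 300 - sin(18 deg) * 90 (side-averaged)
        from wheelperf.simulate import GroundTruth, render_imu

        params = SimulationParams(camber=18.0, gyro_noise_sd=0.0)
        n = 1001
        t = np.arange(n) / 1000.0
        v_lin = np.full(n, params.wheel_circumference / 360.0 * 300.0)
        truth = GroundTruth(
            t=t, v_lin=v_lin, v_rot=np.full(n, 90.0), x=np.zeros(n), y=np.zeros(n),
            trunk_pitch=np.zeros(n), F_push=np.zeros(n), F_roll=np.zeros(n),
        )
        imu = render_imu(truth, params)
        mean_y = 0.5 * (imu.gyro["left_wheel"][:, 1] + imu.gyro["right_wheel"][:, 1])
        expected = 300.0 - math.sin(math.radians(18.0)) * 90.0
        assert np.allclose(mean_y[10:], expected, atol=1e-9)

    def test_ergometer_power_identity(self, sprint_noiseless):
        # summed per-side rim power equals F_push * v_lin pointwise
        params, truth, _, erg = sprint_noiseless
        from wheelperf.lab import instantaneous_power

        po_l, po_r = instantaneous_power(erg)
        fp = np.interp(erg.t, truth.t, truth.F_push)
        v = np.interp(erg.t, truth.t, truth.v_lin)
        assert np.allclose(po_l + po_r, fp * v, atol=1e-9)

    def test_ergometer_zero_force_zero_torque(self):
        params = SimulationParams(push_peak_force=0.0, gyro_noise_sd=0.0)
        _, _, erg = simulate_linear_sprint(params)
        assert np.all(erg.torque_left == 0.0) and np.all(erg.torque_right == 0.0)

    def test_ergometer_requires_sprint_course(self, spider_noiseless):
        params, truth, _ = spider_noiseless
        with pytest.raises(InvalidParameterError):
            render_ergometer(truth, params)


class TestFrontLoadMapping:
    def test_affine_and_clamped(self):
        assert front_load_fraction(0.0, 0.3, 0.3 / 45) == pytest.approx(0.3)
        assert front_load_fraction(45.0, 0.3, 0.3 / 45) == pytest.approx(0.6)
        assert front_load_fraction(1000.0, 0.3, 0.3 / 45) == 1.0
        assert front_load_fraction(-1000.0, 0.3, 0.3 / 45) == 0.0


class TestCohort:
    def test_noiseless_association_is_perfect(self):
        df = simulate_cohort(9, 9, assoc_r2=1.0, seed=1)
        from wheelperf.stats import fit_association

        fit = fit_association(df["lab_sprint_po_mean"], df["field_sprint_po_mean"])
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_effect_separates_groups(self):
        df = simulate_cohort(9, 9, effect=2.0, seed=2)
        elite = df[df.group == "elite"]["lab_sprint_po_mean"].mean()
        amateur = df[df.group == "amateur"]["lab_sprint_po_mean"].mean()
        assert elite > amateur

    def test_duration_outcomes_favor_elite_downward(self):
        df = simulate_cohort(20, 20, effect=2.0, seed=3)
        elite = df[df.group == "elite"]["field_sprint_duration"].mean()
        amateur = df[df.group == "amateur"]["field_sprint_duration"].mean()
        assert elite < amateur

    def test_invalid_r2_rejected(self):
        with pytest.raises(InvalidParameterError):
            simulate_cohort(9, 9, assoc_r2=1.5)

    def test_seed_reproducible(self):
        a = simulate_cohort(9, 9, seed=4)
        b = simulate_cohort(9, 9, seed=4)
        assert a.equals(b)
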