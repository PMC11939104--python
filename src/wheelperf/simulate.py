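"""Forward simulation of the wheelchair-athlete system with ground truth.

The simulator renders the two measurement modalities the pipeline
consumes -- a dual-roller ergometer trace (per-side torque and wheel
velocity at 100 Hz) and a four-sensor gyroscope recording (both wheel
hubs, frame, chest at 200 Hz) -- from a known forward model, so every
downstream stage can be validated against exact ground truth.

Model
-----
Straight-line dynamics are a point mass ``m_total`` driven by a train of
half-sine push bursts and braked by rolling resistance

    F_roll(t) = g * m_total * (f(theta) * mu_front + (1 - f(theta)) * mu_rear)

where ``f(theta)`` is the trunk-pitch-dependent front-castor load
fraction.  Both forces are velocity independent, so the velocity ODE
reduces to quadrature; it is integrated with a cumulative Simpson rule on
a fixed 1 kHz grid (mid-step force evaluations included), with explicit
clamping episodes at standstill.  Agility courses (Illinois/Spider) are
generated kinematically: trapezoidal speed profiles on straights and
turn-in-place segments at a bounded yaw rate, with phase boundaries
aligned to the common 5 ms grid so trapezoidal heading integration is
exact at both the internal and the IMU rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .errors import (
    DegenerateTrialError,
    InvalidCourseError,
    InvalidParameterError,
)
from .kinematics import ImuRecording
from .lab import ErgometerTrace
from .params import G, TRACK_WIDTH, CourseSpec, SimulationParams, coastdown_course

#: internal integration rate [Hz]
INTERNAL_FS = 1000.0
#: phase boundaries of generated courses snap to this grid [s], the least
#: common multiple of the internal (1 kHz) and IMU (200 Hz) sample steps
_ALIGN = 0.005


@dataclass
class GroundTruth:
    """Noise-free state of one simulated trial on the internal 1 kHz grid.

    ``cycle_bounds``/``cycle_power``/``mean_power`` are only populated for
    sprint trials (push cycles are undefined for agility courses), and
    ``coast_bounds`` only for coast-down trials.
    """

    t: np.ndarray            # s
    v_lin: np.ndarray        # m/s, chair linear velocity (>= 0)
    v_rot: np.ndarray        # deg/s, yaw rate
    x: np.ndarray            # m
    y: np.ndarray            # m
    trunk_pitch: np.ndarray  # deg
    F_push: np.ndarray       # N
    F_roll: np.ndarray       # N, effective resistive force
    start_idx: Optional[int] = None
    end_idx: Optional[int] = None
    duration: Optional[float] = None      # s, start rule -> end rule
    cycle_bounds: list[tuple[int, int]] = field(default_factory=list)
    cycle_power: Optional[np.ndarray] = None   # W per cycle
    mean_power: Optional[float] = None         # W, time-weighted cycle mean
    coast_bounds: Optional[tuple[int, int]] = None

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


# ---------------------------------------------------------------------------
# building blocks


def _push_force_train(t: np.ndarray, params: SimulationParams) -> np.ndarray:
    """Half-sine push bursts: peak force, width push_duration, period
    cycle_period, n_pushes bursts starting at t = 0."""
    if params.n_pushes == 0 or params.push_peak_force == 0.0:
        return np.zeros_like(t)
    idx = np.floor(t / params.cycle_period)
    phase = t - idx * params.cycle_period
    active = (idx < params.n_pushes) & (phase < params.push_duration)
    burst = params.push_peak_force * np.sin(np.pi * phase / params.push_duration)
    return np.where(active, burst, 0.0)


def _trunk_pitch_at(t: np.ndarray, schedule: Sequence[tuple[float, float]]) -> np.ndarray:
    ts = np.asarray([p[0] for p in schedule], dtype=float)
    vals = np.asarray([p[1] for p in schedule], dtype=float)
    return np.interp(t, ts, vals)


def front_load_fraction(
    trunk_pitch, base: float, per_deg: float
) -> np.ndarray:
    """Affine, clamped trunk-pitch -> front-castor load-fraction mapping."""
    return np.clip(base + per_deg * np.asarray(trunk_pitch, dtype=float), 0.0, 1.0)


def rolling_force(trunk_pitch, params: SimulationParams) -> np.ndarray:
    """Nominal rolling-resistance force [N] while the chair is moving."""
    f = front_load_fraction(trunk_pitch, params.front_load_base, params.front_load_per_deg)
    mu_eff = f * params.mu_front + (1.0 - f) * params.mu_rear
    return G * params.m_total * mu_eff


def _clamped_cumulative(dv: np.ndarray, g_end: np.ndarray, v0: float = 0.0) -> np.ndarray:
    """Cumulative velocity with standstill clamping.

    ``dv`` are per-step Simpson increments; ``g_end`` the acceleration at
    sample points.  Whenever the integral would go negative the chair is
    held at rest until the net drive acceleration turns positive again.
    """
    n = dv.size
    v = np.empty(n + 1)
    v[0] = v0
    np.cumsum(dv, out=v[1:])
    v[1:] += v0
    for _ in range(10_000):  # episodes, not samples; typically < 5
        neg = np.nonzero(v < -1e-12)[0]
        if neg.size == 0:
            break
        j = int(neg[0])
        restart = np.nonzero(g_end[j:] > 0.0)[0]
        if restart.size == 0:
            v[j:] = 0.0
            break
        k = j + int(restart[0])
        v[j : k + 1] = 0.0
        if k < n:
            v[k + 1 :] = np.cumsum(dv[k:])
    np.maximum(v, 0.0, out=v)
    return v


def _integrate_straight(
    params: SimulationParams,
    n_pushes: int,
    duration: float,
    pitch_schedule: Sequence[tuple[float, float]],
) -> tuple[np.ndarray, ...]:
    """Integrate the straight-line dynamics at the internal rate.

    Returns ``(t, v, x, F_push, F_roll_eff, pitch)``.
    """
    p = replace(params, n_pushes=n_pushes)
    fs = INTERNAL_FS
    n = int(round(duration * fs))
    t = np.arange(n + 1) / fs
    tm = t[:-1] + 0.5 / fs  # mid-step times
    m = params.m_total

    fp_e = _push_force_train(t, p)
    fp_m = _push_force_train(tm, p)
    pitch_e = _trunk_pitch_at(t, pitch_schedule)
    pitch_m = _trunk_pitch_at(tm, pitch_schedule)
    fr_e = rolling_force(pitch_e, params)
    fr_m = rolling_force(pitch_m, params)

    g_end = (fp_e - fr_e) / m
    g_mid = (fp_m - fr_m) / m
    dv = (1.0 / fs) / 6.0 * (g_end[:-1] + 4.0 * g_mid + g_end[1:])
    v = _clamped_cumulative(dv, g_end)
    x = cumulative_trapezoid(v, t, initial=0.0)
    # at standstill static friction balances the (sub-threshold) push force
    fr_eff = np.where(v > 1e-12, fr_e, np.minimum(fp_e, fr_e))
    return t, v, x, fp_e, fr_eff, pitch_e


def _cycle_energy_power(
    t: np.ndarray,
    v: np.ndarray,
    f_roll: np.ndarray,
    m_total: float,
    bounds: tuple[int, int],
) -> float:
    """Per-cycle power: rolling-resistance loss plus kinetic-energy change,
    divided by cycle time."""
    i0, i1 = bounds
    T = float(t[i1] - t[i0])
    loss = float(np.trapezoid(f_roll[i0 : i1 + 1] * v[i0 : i1 + 1], t[i0 : i1 + 1]))
    dke = 0.5 * m_total * (float(v[i1]) ** 2 - float(v[i0]) ** 2)
    return (loss + dke) / T


def _sprint_truth(params: SimulationParams, duration: float) -> GroundTruth:
    t, v, x, fp, fr, pitch = _integrate_straight(
        params, params.n_pushes, duration, params.course.posture_schedule
    )
    truth = GroundTruth(
        t=t,
        v_lin=v,
        v_rot=np.zeros_like(t),
        x=x,
        y=np.zeros_like(t),
        trunk_pitch=pitch,
        F_push=fp,
        F_roll=fr,
    )
    above = np.nonzero(v > 0.1)[0]
    if above.size == 0:
        return truth  # zero-input case: no window, no cycles
    start = int(above[0])
    dist = x - x[start]
    reached = np.nonzero(dist >= 10.0)[0]
    end = int(reached[0]) if reached.size else int(t.size - 1)
    truth.start_idx, truth.end_idx = start, end
    truth.duration = float(t[end] - t[start])

    onsets = [
        int(round(i * params.cycle_period * INTERNAL_FS))
        for i in range(1, params.n_pushes)
    ]
    interior = [i for i in onsets if start < i < end]
    edges = [start] + interior + [end]
    truth.cycle_bounds = list(zip(edges[:-1], edges[1:]))
    truth.cycle_power = np.array(
        [_cycle_energy_power(t, v, fr, params.m_total, b) for b in truth.cycle_bounds]
    )
    Ts = np.array([t[b] - t[a] for a, b in truth.cycle_bounds])
    truth.mean_power = float(np.sum(truth.cycle_power * Ts) / np.sum(Ts))
    return truth


# ---------------------------------------------------------------------------
# sensor rendering


def render_imu(
    truth: GroundTruth,
    params: SimulationParams,
    rng: Optional[np.random.Generator] = None,
) -> ImuRecording:
    """Render the four-gyroscope recording implied by the ground truth.

    Wheel spin gyroscopes see the camber-coupled yaw term subtracted (the
    inverse of the camber correction the pipeline applies), and the two
    wheels get differential speeds ``v -/+ (track/2) * omega`` while
    turning.  I.i.d. Gaussian noise of ``gyro_noise_sd`` deg/s is added to
    every gyro channel; the chest pitch angle is rendered noise-free.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    rate = params.imu_sample_rate
    n = int(np.floor(float(truth.t[-1]) * rate)) + 1
    t = np.arange(n) / rate

    v = np.interp(t, truth.t, truth.v_lin)
    w = np.interp(t, truth.t, truth.v_rot)        # deg/s
    pitch = np.interp(t, truth.t, truth.trunk_pitch)

    w_rad = np.deg2rad(w)
    v_left = v - 0.5 * TRACK_WIDTH * w_rad
    v_right = v + 0.5 * TRACK_WIDTH * w_rad
    wc = params.wheel_circumference
    sin_c = math.sin(math.radians(params.camber))
    gy_left = (360.0 / wc) * v_left - sin_c * w
    gy_right = (360.0 / wc) * v_right - sin_c * w

    def chans(x_ax, y_ax, z_ax):
        out = np.column_stack([x_ax, y_ax, z_ax])
        if params.gyro_noise_sd > 0:
            out = out + rng.normal(0.0, params.gyro_noise_sd, out.shape)
        return out

    zeros = np.zeros(n)
    gyro = {
        "left_wheel": chans(zeros, gy_left, zeros),
        "right_wheel": chans(zeros, gy_right, zeros),
        "frame": chans(zeros, zeros, w),
        "chest": chans(zeros, zeros, zeros),
    }
    return ImuRecording(
        t=t,
        gyro=gyro,
        chest_pitch=pitch,
        wheel_circumference=wc,
        camber=params.camber,
    )


def render_ergometer(truth: GroundTruth, params: SimulationParams) -> ErgometerTrace:
    """Render the per-side ergometer trace: each hand contributes half the
    push force as rim torque, both rollers see the chair velocity."""
    if params.course.kind != "sprint":
        raise InvalidParameterError("ergometer traces are rendered for sprint courses only")
    rate = params.erg_sample_rate
    n = int(np.floor(float(truth.t[-1]) * rate)) + 1
    t = np.arange(n) / rate
    fp = np.interp(t, truth.t, truth.F_push)
    v = np.interp(t, truth.t, truth.v_lin)
    torque = 0.5 * fp * params.wheel_radius
    return ErgometerTrace(
        t=t,
        torque_left=torque.copy(),
        torque_right=torque.copy(),
        v_left=v.copy(),
        v_right=v.copy(),
        wheel_radius=params.wheel_radius,
        body_mass=params.body_mass,
    )


# ---------------------------------------------------------------------------
# trial-level simulators


def simulate_linear_sprint(
    params: SimulationParams,
) -> tuple[GroundTruth, ImuRecording, ErgometerTrace]:
    """Simulate a straight sprint and render both sensor modalities."""
    if params.course.kind != "sprint":
        raise InvalidParameterError("simulate_linear_sprint requires a sprint course")
    duration = params.n_pushes * params.cycle_period + 2.0
    truth = _sprint_truth(params, duration)
    imu = render_imu(truth, params)
    erg = render_ergometer(truth, params)
    return truth, imu, erg


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _straight_profile(L: float, v_max: float, a: float, tau: np.ndarray) -> np.ndarray:
    """Trapezoidal (or triangular) speed profile covering distance L,
    evaluated at local times ``tau``."""
    v_p = min(v_max, math.sqrt(a * L))
    t1 = v_p / a
    t_cruise = max(L - v_p * v_p / a, 0.0) / v_p
    t_end = 2.0 * t1 + t_cruise
    v = np.zeros_like(tau)
    up = tau < t1
    v[up] = a * tau[up]
    mid = (tau >= t1) & (tau < t1 + t_cruise)
    v[mid] = v_p
    down = (tau >= t1 + t_cruise) & (tau < t_end)
    v[down] = a * (t_end - tau[down])
    return v


def simulate_course(params: SimulationParams) -> tuple[GroundTruth, ImuRecording]:
    """Simulate an Illinois or Spider trial by following the waypoints.

    Straights use trapezoidal speed profiles; heading changes happen in
    place at a yaw rate bounded by ``course.yaw_rate_max`` (reached
    exactly whenever the turn time is a multiple of the 5 ms grid).
    """
    course = params.course
    if course.kind not in ("illinois", "spider"):
        raise InvalidParameterError("simulate_course requires an illinois or spider course")
    wp = [np.asarray(p, dtype=float) for p in course.waypoints]
    if len(wp) < 2:
        raise InvalidCourseError("a course needs at least 2 waypoints")

    dt = 1.0 / INTERNAL_FS
    stride = int(round(_ALIGN / dt))  # samples per alignment step
    lead = int(round(0.5 / dt))

    v_parts = [np.zeros(lead)]
    w_parts = [np.zeros(lead)]
    heading = math.atan2(wp[1][1] - wp[0][1], wp[1][0] - wp[0][0])
    psi0 = heading
    for i in range(len(wp) - 1):
        p, q = wp[i], wp[i + 1]
        seg = q - p
        L = float(np.hypot(seg[0], seg[1]))
        if L < 1e-12:
            continue
        target = math.atan2(seg[1], seg[0])
        if i > 0:
            dpsi = _wrap_angle(target - heading)
            if abs(dpsi) > 1e-12:
                t_turn = abs(math.degrees(dpsi)) / course.yaw_rate_max
                n_turn = max(stride, int(math.ceil(t_turn / _ALIGN - 1e-9)) * stride)
                rate = math.degrees(dpsi) / (n_turn * dt)
                w_parts.append(np.full(n_turn, rate))
                v_parts.append(np.zeros(n_turn))
                heading = target
        v_p = min(course.v_max, math.sqrt(course.accel * L))
        t_seg = 2.0 * v_p / course.accel + max(L - v_p * v_p / course.accel, 0.0) / v_p
        n_seg = int(math.ceil(t_seg / _ALIGN - 1e-9)) * stride
        tau = np.arange(n_seg) * dt
        v_parts.append(_straight_profile(L, course.v_max, course.accel, tau))
        w_parts.append(np.zeros(n_seg))
    tail = int(round(1.0 / dt))
    v_parts.append(np.zeros(tail + 1))
    w_parts.append(np.zeros(tail + 1))

    v = np.concatenate(v_parts)
    w = np.concatenate(w_parts)
    t = np.arange(v.size) * dt
    psi = psi0 + cumulative_trapezoid(np.deg2rad(w), t, initial=0.0)
    x = wp[0][0] + cumulative_trapezoid(v * np.cos(psi), t, initial=0.0)
    y = wp[0][1] + cumulative_trapezoid(v * np.sin(psi), t, initial=0.0)
    pitch = _trunk_pitch_at(t, course.posture_schedule)

    truth = GroundTruth(
        t=t,
        v_lin=v,
        v_rot=w,
        x=x,
        y=y,
        trunk_pitch=pitch,
        F_push=np.zeros_like(t),
        F_roll=np.zeros_like(t),
    )
    above = np.nonzero(v > 0.1)[0]
    if above.size:
        start = int(above[0])
        u = np.array([math.cos(psi0), math.sin(psi0)])
        s = (x - wp[0][0]) * u[0] + (y - wp[0][1]) * u[1]
        crossing = np.nonzero((s[:-1] > 0.0) & (s[1:] <= 0.0))[0] + 1
        crossing = crossing[t[crossing] >= t[start] + 2.0]
        if crossing.size:
            end = int(crossing[-1])
            truth.start_idx, truth.end_idx = start, end
            truth.duration = float(t[end] - t[start])
    return truth, render_imu(truth, params)


def simulate_coastdown_pair(
    params: SimulationParams,
) -> list[tuple[GroundTruth, ImuRecording]]:
    """Simulate the four-trial coast-down protocol.

    Two pushes bring the chair up to speed, then it decelerates freely
    with the hands on the knees; trials 1-2 are upright, trials 3-4 in
    the forward-bent posture (fixed trunk pitch per trial, taken from the
    course's two-entry posture schedule).
    """
    course = params.course
    if course.kind != "coastdown":
        raise InvalidParameterError("simulate_coastdown_pair requires a coastdown course")
    if len(course.posture_schedule) < 2:
        raise InvalidParameterError("coastdown posture_schedule needs upright and forward entries")
    upright = course.posture_schedule[0][1]
    forward = course.posture_schedule[1][1]
    pitches = [upright, upright, forward, forward]

    duration = 2 * params.cycle_period + 8.0
    trials: list[tuple[GroundTruth, ImuRecording]] = []
    for k, pitch in enumerate(pitches):
        t, v, x, fp, fr, pitch_arr = _integrate_straight(
            params, 2, duration, ((0.0, pitch),)
        )
        coast_start = int(round((params.cycle_period + params.push_duration) * INTERNAL_FS)) + 1
        if v[coast_start] <= 0.3:
            raise DegenerateTrialError(
                f"velocity after pushes is {v[coast_start]:.2f} m/s (<= 0.3 m/s)"
            )
        stopped = np.nonzero(v[coast_start:] <= 0.02)[0]
        coast_end = coast_start + int(stopped[0]) if stopped.size else int(t.size - 1)
        truth = GroundTruth(
            t=t,
            v_lin=v,
            v_rot=np.zeros_like(t),
            x=x,
            y=np.zeros_like(t),
            trunk_pitch=pitch_arr,
            F_push=fp,
            F_roll=fr,
            coast_bounds=(coast_start, coast_end),
        )
        rng = np.random.default_rng([params.seed, k])
        trials.append((truth, render_imu(truth, params, rng=rng)))
    return trials


# ---------------------------------------------------------------------------
# cohort generator


#: outcome name -> (modality, center, scale, sign); sign -1 marks
#: "lower is better" outcomes (test durations)
COHORT_OUTCOMES: dict[str, tuple[str, float, float, int]] = {
    "lab_sprint_po_mean": ("lab", 1.65, 0.70, +1),
    "lab_sprint_v_peak": ("lab", 3.05, 0.55, +1),
    "lab_wingate_p30": ("lab", 1.85, 0.75, +1),
    "field_sprint_po_mean": ("field", 1.55, 0.80, +1),
    "field_sprint_v_peak_lin": ("field", 3.90, 0.80, +1),
    "field_sprint_duration": ("field", 4.20, 0.80, -1),
    "field_illinois_v_peak_lin": ("field", 3.40, 0.70, +1),
    "field_illinois_v_peak_rot": ("field", 206.0, 37.0, +1),
    "field_illinois_duration": ("field", 25.1, 7.5, -1),
    "field_spider_v_peak_rot": ("field", 218.0, 46.0, +1),
    "field_spider_duration": ("field", 20.0, 5.0, -1),
}


def simulate_cohort(
    n_elite: int,
    n_amateur: int,
    effect: float = 2.0,
    assoc_r2: float = 0.85,
    seed: int = 0,
    curvilinear: bool = False,
) -> pd.DataFrame:
    """Draw a synthetic elite/amateur cohort with controlled structure.

    Each player has a latent ability (elite mean shifted by ``effect``
    SD).  Lab and field outcomes are noisy affine renderings of ability,
    with symmetric noise variances chosen so the population R-squared of
    any field outcome regressed on any lab outcome equals ``assoc_r2``
    (exactly in the linear case).  With ``curvilinear=True`` field
    outcomes gain a mild quadratic component of ability.
    """
    if n_elite < 2 or n_amateur < 2:
        raise InvalidParameterError("group sizes must be >= 2")
    if not 0.0 <= assoc_r2 <= 1.0:
        raise InvalidParameterError("assoc_r2 must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = n_elite + n_amateur
    groups = np.array(["amateur"] * n_amateur + ["elite"] * n_elite)
    ability = rng.normal(0.0, 1.0, n)
    ability[groups == "elite"] += effect

    p = n_elite / n
    var_a = 1.0 + p * (1.0 - p) * effect**2
    if assoc_r2 > 0.0:
        noise_var = var_a * (1.0 / math.sqrt(assoc_r2) - 1.0)
    else:
        noise_var = None  # field outcomes become pure noise

    data: dict[str, np.ndarray] = {
        "player": np.arange(1, n + 1),
        "group": groups,
    }
    for name, (modality, center, scale, sign) in COHORT_OUTCOMES.items():
        if modality == "field" and curvilinear:
            core = ability + 0.12 * (ability**2 - var_a)
        else:
            core = ability.copy()
        if noise_var is None:
            if modality == "field":
                core = rng.normal(0.0, math.sqrt(var_a), n)
            noise = np.zeros(n)
        else:
            noise = rng.normal(0.0, math.sqrt(noise_var), n)
        z = core + noise
        sd = math.sqrt(var_a + (0.0 if noise_var is None else noise_var))
        data[name] = center + sign * scale * (z / sd)
    return pd.DataFrame(data)
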