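"""IMU-based wheelchair kinematics: camber correction, velocities,
trajectory, and field-test timing/peak outcomes.

The wheel-hub gyroscope's spin axis is inclined by the camber angle, so
frame yaw leaks into the measured wheel speed; the correction

    v_ang = GyroY_wheel + sin(camber) * GyroZ_frame    [deg/s]

recovers the true angular wheel velocity, which converts to linear
velocity through the wheel circumference, ``v_lin = WC / 360 * v_ang``.
Yaw rate is taken directly from the frame Z gyroscope.  Field-test
timing uses the start rule (side-averaged linear velocity > 0.1 m/s),
the 10 m mean-wheel-distance rule for the sprint, and the zero-line
(start line) re-crossing rule for the Illinois and Spider tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt, lfilter

from .errors import (
    AlignmentError,
    IncompleteTestError,
    InvalidInputError,
    InvalidParameterError,
    InvalidRateError,
    InvalidWindowError,
    MissingSensorError,
    NoMotionError,
)

SENSORS = ("left_wheel", "right_wheel", "frame", "chest")
FIELD_TESTS = ("sprint", "illinois", "spider")
START_THRESHOLD = 0.1   # m/s
SPRINT_DISTANCE = 10.0  # m
MIN_COURSE_TIME = 2.0   # s before a zero-line crossing may end the trial


@dataclass
class ImuRecording:
    """Synchronized four-sensor gyroscope recording.

    ``gyro`` maps sensor name to an ``(n, 3)`` array of X/Y/Z rates in
    deg/s.  The wheel spin axis is Y; frame yaw is Z.  ``chest_pitch`` is
    the trunk inclination in degrees (0 = upright).
    """

    t: np.ndarray
    gyro: dict[str, np.ndarray]
    chest_pitch: Optional[np.ndarray]
    wheel_circumference: float  # m
    camber: float               # deg

    def __post_init__(self) -> None:
        if self.wheel_circumference <= 0:
            raise InvalidParameterError("wheel_circumference must be > 0")
        if abs(self.camber) >= 45.0:
            raise InvalidParameterError("|camber| must be < 45 deg")
        n = self.t.size
        for name, arr in self.gyro.items():
            if arr.shape[0] != n:
                raise AlignmentError(f"sensor {name!r} length differs from time base")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class FieldKinematics:
    """Derived kinematic series plus the detected analysis window."""

    t: np.ndarray
    v_lin: np.ndarray          # m/s, side-averaged
    v_lin_left: np.ndarray
    v_lin_right: np.ndarray
    v_rot: np.ndarray          # deg/s
    distance_left: np.ndarray  # m, from the start sample
    distance_right: np.ndarray
    x: np.ndarray
    y: np.ndarray
    start_idx: int
    end_idx: int

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class FieldOutcomes:
    """Headline field outcomes; fields undefined for a test are None."""

    test: str
    duration: float                      # s
    v_peak_lin: Optional[float] = None   # m/s (sprint, illinois)
    v_peak_rot: Optional[float] = None   # deg/s (illinois, spider)
    po_mean: Optional[float] = None      # W/kg, filled by the power stage


def filter_imu(
    series: np.ndarray, fs: float, cutoff: float = 10.0, order: int = 2, zero_phase: bool = False
) -> np.ndarray:
    """Low-pass Butterworth for the field path (2nd order, 10 Hz).

    The default is a causal single-pass (recursive) filter; set
    ``zero_phase=True`` for forward-backward filtering.
    """
    if fs <= 2.0 * cutoff:
        raise InvalidRateError(f"fs={fs} Hz too low for a {cutoff} Hz cutoff")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    x = np.asarray(series, dtype=float)
    if zero_phase:
        return filtfilt(b, a, x)
    return lfilter(b, a, x)


def _maybe_filter(series: np.ndarray, fs: float, mode: str) -> np.ndarray:
    if mode == "none":
        return np.asarray(series, dtype=float)
    if mode == "causal":
        return filter_imu(series, fs)
    if mode == "zero_phase":
        return filter_imu(series, fs, zero_phase=True)
    raise InvalidParameterError(f"unknown filter mode {mode!r}")


def camber_correct(gyro_y_wheel: np.ndarray, gyro_z_frame: np.ndarray, camber: float) -> np.ndarray:
    """Camber-corrected angular wheel velocity [deg/s]."""
    gy = np.asarray(gyro_y_wheel, dtype=float)
    gz = np.asarray(gyro_z_frame, dtype=float)
    if gy.shape != gz.shape:
        raise AlignmentError("wheel and frame gyro series differ in length")
    return gy + math.sin(math.radians(camber)) * gz


def to_linear(v_ang: np.ndarray, wheel_circumference: float) -> np.ndarray:
    """Linear velocity [m/s] from angular wheel velocity [deg/s]."""
    if wheel_circumference <= 0:
        raise InvalidParameterError("wheel_circumference must be > 0")
    return wheel_circumference / 360.0 * np.asarray(v_ang, dtype=float)


def rotational_velocity(recording: ImuRecording, filter_mode: str = "causal") -> np.ndarray:
    """Yaw rate [deg/s]: the (filtered) frame Z gyroscope."""
    if "frame" not in recording.gyro:
        raise MissingSensorError("frame")
    return _maybe_filter(recording.gyro["frame"][:, 2], recording.fs, filter_mode)


def detect_start(v_lin: np.ndarray, threshold: float = START_THRESHOLD) -> int:
    """First sample at which linear velocity exceeds the threshold."""
    v = np.asarray(v_lin, dtype=float)
    if v[0] > threshold:
        raise InvalidInputError("series starts above the start threshold")
    above = np.nonzero(v > threshold)[0]
    if above.size == 0:
        raise NoMotionError(f"velocity never exceeds {threshold} m/s")
    return int(above[0])


def detect_sprint_end(
    distance_left: np.ndarray,
    distance_right: np.ndarray,
    target: float = SPRINT_DISTANCE,
) -> int:
    """First sample at which the mean wheel distance reaches ``target`` m."""
    mean_dist = 0.5 * (np.asarray(distance_left) + np.asarray(distance_right))
    reached = np.nonzero(mean_dist >= target)[0]
    if reached.size == 0:
        raise IncompleteTestError(f"mean wheel distance never reaches {target} m")
    return int(reached[0])


def dead_reckon(v_lin: np.ndarray, v_rot: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Trajectory by dead reckoning: integrate yaw rate into heading and
    linear velocity along it (trapezoid rule)."""
    v = np.asarray(v_lin, dtype=float)
    w = np.asarray(v_rot, dtype=float)
    if v.shape != w.shape:
        raise AlignmentError("v_lin and v_rot differ in length")
    dt = 1.0 / fs
    psi = cumulative_trapezoid(np.deg2rad(w), dx=dt, initial=0.0)
    x = cumulative_trapezoid(v * np.cos(psi), dx=dt, initial=0.0)
    y = cumulative_trapezoid(v * np.sin(psi), dx=dt, initial=0.0)
    return x, y


def detect_course_end(
    x: np.ndarray,
    y: np.ndarray,
    t: np.ndarray,
    start_idx: int,
    heading0: Optional[float] = None,
    min_time: float = MIN_COURSE_TIME,
) -> int:
    """Last re-crossing of the zero line (start line).

    The zero line passes through the start position perpendicular to the
    initial heading; the trial ends at the last sample whose forward
    coordinate changes sign from positive to non-positive, at least
    ``min_time`` seconds after the start (launch wobble is ignored).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if heading0 is None:
        # direction of the first 0.25 m of travel
        dx = x - x[start_idx]
        dy = y - y[start_idx]
        d = np.hypot(dx, dy)
        ahead = np.nonzero(d[start_idx:] > 0.25)[0]
        if ahead.size == 0:
            raise IncompleteTestError("trial never leaves the start line")
        j = start_idx + int(ahead[0])
        heading0 = math.atan2(dy[j], dx[j])
    s = (x - x[start_idx]) * math.cos(heading0) + (y - y[start_idx]) * math.sin(heading0)
    crossing = np.nonzero((s[:-1] > 0.0) & (s[1:] <= 0.0))[0] + 1
    crossing = crossing[np.asarray(t)[crossing] >= t[start_idx] + min_time]
    if crossing.size == 0:
        raise IncompleteTestError("trajectory never re-crosses the start line")
    return int(crossing[-1])


def wheel_linear_velocities(
    recording: ImuRecording, filter_mode: str = "causal"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-wheel camber-corrected linear velocities [m/s]."""
    for sensor in ("left_wheel", "right_wheel", "frame"):
        if sensor not in recording.gyro:
            raise MissingSensorError(sensor)
    fs = recording.fs
    gz = _maybe_filter(recording.gyro["frame"][:, 2], fs, filter_mode)
    out = []
    for side in ("left_wheel", "right_wheel"):
        gy = _maybe_filter(recording.gyro[side][:, 1], fs, filter_mode)
        v_ang = camber_correct(gy, gz, recording.camber)
        out.append(to_linear(v_ang, recording.wheel_circumference))
    return out[0], out[1]


def process_recording(
    recording: ImuRecording,
    test: str,
    filter_mode: str = "causal",
    start_threshold: float = START_THRESHOLD,
    sprint_distance: float = SPRINT_DISTANCE,
) -> FieldKinematics:
    """Full kinematics pipeline for one field trial.

    Computes camber-corrected per-wheel and side-averaged linear
    velocity, yaw rate, per-wheel distances, the dead-reckoned
    trajectory, and the test-specific start/end window.
    """
    if test not in FIELD_TESTS:
        raise InvalidParameterError(f"unknown field test {test!r}")
    fs = recording.fs
    vl, vr = wheel_linear_velocities(recording, filter_mode)
    v = 0.5 * (vl + vr)
    v_rot = rotational_velocity(recording, filter_mode)

    start = detect_start(v, start_threshold)
    dl = cumulative_trapezoid(vl, recording.t, initial=0.0)
    dr = cumulative_trapezoid(vr, recording.t, initial=0.0)
    dl -= dl[start]
    dr -= dr[start]
    x, y = dead_reckon(v, v_rot, fs)

    if test == "sprint":
        end = detect_sprint_end(dl, dr, sprint_distance)
    else:
        psi = cumulative_trapezoid(np.deg2rad(v_rot), dx=1.0 / fs, initial=0.0)
        end = detect_course_end(x, y, recording.t, start, heading0=float(psi[start]))
    return FieldKinematics(
        t=recording.t,
        v_lin=v,
        v_lin_left=vl,
        v_lin_right=vr,
        v_rot=v_rot,
        distance_left=dl,
        distance_right=dr,
        x=x,
        y=y,
        start_idx=start,
        end_idx=end,
    )


def field_outcomes(kin: FieldKinematics, test: str) -> FieldOutcomes:
    """Timing and peak outcomes for one trial.

    Peak linear velocity is reported for the sprint and Illinois tests,
    peak rotational velocity (absolute value) for Illinois and Spider;
    duration for all three.
    """
    if test not in FIELD_TESTS:
        raise InvalidParameterError(f"unknown field test {test!r}")
    if kin.end_idx <= kin.start_idx:
        raise InvalidWindowError("empty analysis window")
    sl = slice(kin.start_idx, kin.end_idx + 1)
    duration = float(kin.t[kin.end_idx] - kin.t[kin.start_idx])
    out = FieldOutcomes(test=test, duration=duration)
    if test in ("sprint", "illinois"):
        out.v_peak_lin = float(np.max(kin.v_lin[sl]))
    if test in ("illinois", "spider"):
        out.v_peak_rot = float(np.max(np.abs(kin.v_rot[sl])))
    return out
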