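"""Lab ergometer processing: sprint and Wingate outcomes.

A dual-roller wheelchair ergometer measures per-side rim torque ``M``
[Nm] and wheel velocity ``v_w`` [m/s] at 100 Hz.  Instantaneous power per
side is ``PO = M / r_w * v_w``; the sprint outcome is the summed-side
power averaged over the first 10 m and normalized to body mass, the
Wingate outcome (P30) the same average over 30 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal import butter, filtfilt

from .errors import (
    IncompleteTestError,
    InvalidParameterError,
    InvalidRateError,
    NoMotionError,
)

START_THRESHOLD = 0.1  # m/s, same rule as the field start detection
SPRINT_DISTANCE = 10.0  # m
WINGATE_DURATION = 30.0  # s


@dataclass
class ErgometerTrace:
    """Uniformly sampled per-side ergometer recording."""

    t: np.ndarray
    torque_left: np.ndarray   # Nm
    torque_right: np.ndarray  # Nm
    v_left: np.ndarray        # m/s
    v_right: np.ndarray       # m/s
    wheel_radius: float       # m
    body_mass: float          # kg

    def __post_init__(self) -> None:
        n = self.t.size
        for name in ("torque_left", "torque_right", "v_left", "v_right"):
            if getattr(self, name).size != n:
                raise InvalidParameterError(f"{name} length differs from time base")
        if self.wheel_radius <= 0:
            raise InvalidParameterError("wheel_radius must be > 0")
        if self.body_mass <= 0:
            raise InvalidParameterError("body_mass must be > 0")

    @property
    def fs(self) -> float:
        return 1.0 / float(self.t[1] - self.t[0])


@dataclass
class LabOutcomes:
    """Headline lab outcomes (mass-normalized powers)."""

    po_mean: Optional[float] = None  # W/kg over the first 10 m
    v_peak: Optional[float] = None   # m/s within the 10 m window
    p30: Optional[float] = None      # W/kg over 30 s
    window: Optional[tuple[int, int]] = None


def filter_lab(series: np.ndarray, fs: float, cutoff: float = 10.0, order: int = 4) -> np.ndarray:
    """Zero-phase low-pass Butterworth (4th order, 10 Hz) for the lab path.

    Zero-phase filtering preserves peak timing, which matters for the
    peak-velocity outcome.
    """
    if fs <= 2.0 * cutoff:
        raise InvalidRateError(f"fs={fs} Hz too low for a {cutoff} Hz cutoff")
    b, a = butter(order, cutoff, btype="low", fs=fs)
    return filtfilt(b, a, np.asarray(series, dtype=float))


def instantaneous_power(trace: ErgometerTrace) -> tuple[np.ndarray, np.ndarray]:
    """Per-side instantaneous power PO = M / r_w * v_w [W].

    Negative values (braking on the rim) are retained.
    """
    if trace.wheel_radius <= 0:
        raise InvalidParameterError("wheel_radius must be > 0")
    po_left = trace.torque_left / trace.wheel_radius * trace.v_left
    po_right = trace.torque_right / trace.wheel_radius * trace.v_right
    return po_left, po_right


def _lab_start(v_avg: np.ndarray, threshold: float = START_THRESHOLD) -> int:
    """First sample above the start threshold; a trace already moving at
    t=0 starts at sample 0 with a warning."""
    if v_avg[0] > threshold:
        warnings.warn("trace does not start from standstill; window starts at sample 0")
        return 0
    above = np.nonzero(v_avg > threshold)[0]
    if above.size == 0:
        raise NoMotionError(f"velocity never exceeds {threshold} m/s")
    return int(above[0])


def sprint_outcomes(trace: ErgometerTrace, distance: float = SPRINT_DISTANCE) -> LabOutcomes:
    """Sprint PO_mean [W/kg] and v_peak [m/s] over the first ``distance`` m.

    The window runs from the start rule (side-averaged velocity > 0.1
    m/s) to the first sample at which the mean cumulative distance of
    both wheels reaches ``distance`` (the crossing sample is included).
    """
    fs = trace.fs
    vl = filter_lab(trace.v_left, fs)
    vr = filter_lab(trace.v_right, fs)
    ml = filter_lab(trace.torque_left, fs)
    mr = filter_lab(trace.torque_right, fs)
    v_avg = 0.5 * (vl + vr)

    start = _lab_start(v_avg)
    dist = cumulative_trapezoid(v_avg, trace.t, initial=0.0)
    dist -= dist[start]
    reached = np.nonzero(dist[start:] >= distance)[0]
    if reached.size == 0:
        raise IncompleteTestError(f"mean wheel distance never reaches {distance} m")
    end = start + int(reached[0])

    po_sum = (ml * vl + mr * vr) / trace.wheel_radius
    sl = slice(start, end + 1)
    duration = float(trace.t[end] - trace.t[start])
    po_mean = float(np.trapezoid(po_sum[sl], trace.t[sl])) / duration / trace.body_mass
    v_peak = float(np.max(v_avg[sl]))
    return LabOutcomes(po_mean=po_mean, v_peak=v_peak, window=(start, end))


def wingate_p30(trace: ErgometerTrace, duration: float = WINGATE_DURATION) -> float:
    """Wingate anaerobic power P30 [W/kg]: summed-side power averaged over
    ``duration`` seconds from the start rule and divided by body mass."""
    fs = trace.fs
    vl = filter_lab(trace.v_left, fs)
    vr = filter_lab(trace.v_right, fs)
    ml = filter_lab(trace.torque_left, fs)
    mr = filter_lab(trace.torque_right, fs)
    v_avg = 0.5 * (vl + vr)

    try:
        start = _lab_start(v_avg)
    except NoMotionError:
        start = 0  # no propulsion at all: P30 is simply zero power
    t_end = trace.t[start] + duration
    if trace.t[-1] + 0.5 / fs < t_end:
        raise IncompleteTestError(f"trace shorter than {duration} s after start")
    end = start + int(round(duration * fs))
    end = min(end, trace.t.size - 1)

    po_sum = (ml * vl + mr * vr) / trace.wheel_radius
    sl = slice(start, end + 1)
    span = float(trace.t[end] - trace.t[start])
    return float(np.trapezoid(po_sum[sl], trace.t[sl])) / span / trace.body_mass
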