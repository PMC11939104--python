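"""Coast-down rolling-resistance estimation.

The protocol: the athlete pushes the chair twice, puts the hands on the
knees and sits still while the chair decelerates freely; two trials are
performed upright and two leaning forward.  The two postures shift
weight between the front castors and rear wheels, which makes the pair
of rolling-resistance coefficients identifiable:

    F_roll_i = m g (f_i * mu_front + (1 - f_i) * mu_rear)

with f_i the front-load fraction of trial i.  Per trial the deceleration
is the least-squares slope of linear velocity over the coast segment,
so F_roll_hat = m * |slope|; the coefficients follow from least squares
over all trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .errors import (
    DegenerateTrialError,
    InconsistentTrialError,
    UnidentifiableSystemError,
)
from .kinematics import ImuRecording, wheel_linear_velocities
from .params import G
from .simulate import front_load_fraction

MIN_COAST_LEN = 1.5   # s
SETTLE_TIME = 0.3     # s after the last push before the window may start
_SMOOTH_WIN = 0.31    # s moving-average window used only for segmentation
_ACCEL_THRESHOLD = 0.2  # m/s^2 on the smoothed series marks a push
_DECREASE_TOL = 2e-4  # m/s per sample slack for "monotone decreasing"
_V_FLOOR = 0.02       # m/s, below this the chair counts as stopped


@dataclass
class CoastDownTrial:
    """One processed coast-down trial."""

    posture: str               # "upright" | "forward"
    trunk_pitch: float         # deg, held during the trial
    m_total: float             # kg
    fitted_decel: float        # m/s^2 (negative)
    F_roll_hat: float          # N
    window: tuple[int, int]    # coast segment sample bounds


@dataclass
class RollingResistanceModel:
    """Per-wheel-pair rolling resistance with trunk-pitch load shifting."""

    mu_front: float
    mu_rear: float
    front_load_base: float = 0.30
    front_load_per_deg: float = 0.30 / 45.0
    g: float = G

    def load_fraction(self, trunk_pitch) -> np.ndarray:
        return front_load_fraction(trunk_pitch, self.front_load_base, self.front_load_per_deg)

    def effective_mu(self, trunk_pitch) -> np.ndarray:
        f = self.load_fraction(trunk_pitch)
        return f * self.mu_front + (1.0 - f) * self.mu_rear


def segment_coast(v_lin: np.ndarray, fs: float, min_len: float = MIN_COAST_LEN) -> tuple[int, int]:
    """Locate the free-deceleration window of a coast-down trial.

    The window starts ``SETTLE_TIME`` after the last positive-acceleration
    episode and spans the longest (tolerantly) monotone-decreasing
    stretch of the smoothed velocity, which must last at least
    ``min_len`` seconds.
    """
    v = np.asarray(v_lin, dtype=float)
    win = max(3, int(round(_SMOOTH_WIN * fs)) | 1)  # odd length
    kernel = np.ones(win) / win
    # edge-padded moving average: zero padding would fabricate a
    # deceleration at the trace boundaries
    v_s = np.convolve(np.pad(v, win // 2, mode="edge"), kernel, mode="valid")
    acc = np.gradient(v_s) * fs

    pushing = np.nonzero(acc > _ACCEL_THRESHOLD)[0]
    # the moving average smears the push end by ~win/2; compensate so the
    # settle time is measured from the true episode end
    last_push = max(int(pushing[-1]) - win // 2, 0) if pushing.size else 0
    i0 = last_push + int(round(SETTLE_TIME * fs))
    if i0 >= v.size - 1:
        raise DegenerateTrialError("no samples after the last push")

    # a stopped chair is flat, not decelerating: keep the window above a
    # small velocity floor
    dec = (np.diff(v_s[i0:]) < _DECREASE_TOL) & (v_s[i0:-1] > _V_FLOOR)
    # longest run of True
    best_start, best_len, run_start, run_len = 0, 0, 0, 0
    for i, d in enumerate(dec):
        if d:
            if run_len == 0:
                run_start = i
            run_len += 1
            if run_len > best_len:
                best_start, best_len = run_start, run_len
        else:
            run_len = 0
    if best_len < int(round(min_len * fs)):
        raise DegenerateTrialError(f"no decreasing stretch of >= {min_len} s")
    a, b = i0 + best_start, i0 + best_start + best_len
    # the tolerance lets flat stretches through; demand a real deceleration
    if (v_s[a] - v_s[b - 1]) * fs / best_len < 0.01:
        raise DegenerateTrialError("candidate window shows no net deceleration")
    return a, b


def fit_F_roll(
    v_window: np.ndarray, fs: float, m_total: float
) -> tuple[float, float]:
    """Least-squares deceleration over the coast window.

    Returns ``(decel [m/s^2, negative], F_roll_hat [N])``.
    """
    v = np.asarray(v_window, dtype=float)
    t = np.arange(v.size) / fs
    slope = float(np.polyfit(t, v, 1)[0])
    if slope >= -1e-12:
        raise InconsistentTrialError(f"coast window has non-negative slope {slope:.4g}")
    return slope, m_total * abs(slope)


def process_trial(
    recording: ImuRecording,
    posture: str,
    m_total: float,
    trunk_pitch: Optional[float] = None,
    filter_mode: str = "causal",
) -> CoastDownTrial:
    """Kinematics + segmentation + slope fit for one coast-down trial."""
    vl, vr = wheel_linear_velocities(recording, filter_mode)
    v = 0.5 * (vl + vr)
    if trunk_pitch is None:
        if recording.chest_pitch is None:
            raise DegenerateTrialError("no trunk pitch available for the trial")
        trunk_pitch = float(np.median(recording.chest_pitch))
    a, b = segment_coast(v, recording.fs)
    decel, f_hat = fit_F_roll(v[a:b], recording.fs, m_total)
    return CoastDownTrial(
        posture=posture,
        trunk_pitch=trunk_pitch,
        m_total=m_total,
        fitted_decel=decel,
        F_roll_hat=f_hat,
        window=(a, b),
    )


def solve_coefficients(
    trials: Sequence[CoastDownTrial],
    front_load_base: float = 0.30,
    front_load_per_deg: float = 0.30 / 45.0,
) -> RollingResistanceModel:
    """Solve the per-wheel-pair coefficients from >= 2 trials.

    Each trial contributes one row ``m g [f_i, 1 - f_i]`` of a linear
    system in ``(mu_front, mu_rear)``, solved by least squares.  Negative
    solutions are clipped to zero with a warning.
    """
    if len(trials) < 2:
        raise UnidentifiableSystemError("need at least two coast-down trials")
    f = front_load_fraction(
        np.array([tr.trunk_pitch for tr in trials]), front_load_base, front_load_per_deg
    )
    if float(np.ptp(f)) < 1e-9:
        raise UnidentifiableSystemError(
            "all trials share one load fraction; mu_front and mu_rear are not separable"
        )
    m = np.array([tr.m_total for tr in trials])
    A = (G * m)[:, None] * np.column_stack([f, 1.0 - f])
    b = np.array([tr.F_roll_hat for tr in trials])
    mu, *_ = np.linalg.lstsq(A, b, rcond=None)
    mu_front, mu_rear = float(mu[0]), float(mu[1])
    if mu_front < 0 or mu_rear < 0:
        warnings.warn(
            f"negative rolling-resistance solution clipped to zero "
            f"(mu_front={mu_front:.4g}, mu_rear={mu_rear:.4g})"
        )
        mu_front = max(mu_front, 0.0)
        mu_rear = max(mu_rear, 0.0)
    return RollingResistanceModel(
        mu_front=mu_front,
        mu_rear=mu_rear,
        front_load_base=front_load_base,
        front_load_per_deg=front_load_per_deg,
    )


def F_roll_series(
    model: RollingResistanceModel, trunk_pitch: np.ndarray, m_total: float
) -> np.ndarray:
    """Trunk-inclination-corrected rolling-resistance force [N]."""
    return model.g * m_total * model.effective_mu(trunk_pitch)
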