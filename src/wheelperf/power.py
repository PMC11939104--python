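"""Per-cycle and mean mechanical power for the field sprint.

With no turning, negligible air resistance and a flat floor, the
mechanical power of one push cycle is the rolling-resistance loss plus
the kinetic-energy change over the cycle:

    po = (1/T) * [ integral_cycle F_roll(t) * v_lin(t) dt
                   + 1/2 * m_total * (v_end^2 - v_start^2) ]

Cycles are segmented at local minima of the (filtered) velocity; because
the kinetic-energy terms telescope and the loss integrals add, the
time-weighted mean power over the sprint window is insensitive to the
exact boundary placement.  Mean power is reported only for the sprint
test (power during turning is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .coastdown import F_roll_series, RollingResistanceModel
from .errors import InvalidCycleError, InvalidInputError
from .kinematics import FieldKinematics

logger = logging.getLogger(__name__)

MIN_CYCLE_SEP = 0.3   # s between cycle boundaries
MIN_PROMINENCE = 0.05  # m/s prominence of a velocity minimum


@dataclass
class PushCycle:
    """One propulsion cycle inside the sprint window."""

    start_idx: int
    end_idx: int
    T: float                  # s
    po: Optional[float] = None  # W


def detect_cycles(
    v_lin: np.ndarray,
    fs: float,
    start_idx: int,
    end_idx: int,
    min_sep: float = MIN_CYCLE_SEP,
    prominence: float = MIN_PROMINENCE,
) -> list[PushCycle]:
    """Cycle boundaries at velocity minima within [start_idx, end_idx].

    Falls back to a single whole-window cycle (logged) when no minima
    are found, e.g. on constant-velocity input.
    """
    if end_idx <= start_idx:
        raise InvalidInputError("empty analysis window")
    v = np.asarray(v_lin, dtype=float)[start_idx : end_idx + 1]
    minima, _ = find_peaks(-v, distance=max(1, int(round(min_sep * fs))), prominence=prominence)
    edges = [start_idx] + [start_idx + int(i) for i in minima] + [end_idx]
    edges = sorted(set(edges))
    if len(edges) < 3:
        logger.warning("no velocity minima found; falling back to a single cycle")
        edges = [start_idx, end_idx]
    dt = 1.0 / fs
    return [
        PushCycle(start_idx=a, end_idx=b, T=(b - a) * dt)
        for a, b in zip(edges[:-1], edges[1:])
    ]


def cycle_power(
    cycle: PushCycle,
    t: np.ndarray,
    v_lin: np.ndarray,
    f_roll: np.ndarray,
    m_total: float,
) -> float:
    """Mechanical power of one cycle [W]; negative values (net braking)
    are retained."""
    i0, i1 = cycle.start_idx, cycle.end_idx
    if i1 <= i0:
        raise InvalidCycleError("zero-length cycle")
    sl = slice(i0, i1 + 1)
    T = float(t[i1] - t[i0])
    loss = float(np.trapezoid(np.asarray(f_roll)[sl] * np.asarray(v_lin)[sl], np.asarray(t)[sl]))
    dke = 0.5 * m_total * (float(v_lin[i1]) ** 2 - float(v_lin[i0]) ** 2)
    return (loss + dke) / T


def mean_field_power(cycles: Sequence[PushCycle], body_mass: float) -> float:
    """Time-weighted mean cycle power, normalized to body mass [W/kg]."""
    if not cycles:
        raise InvalidInputError("empty cycle list")
    if any(c.po is None for c in cycles):
        raise InvalidInputError("cycles must carry per-cycle power")
    Ts = np.array([c.T for c in cycles])
    pos = np.array([c.po for c in cycles])
    return float(np.sum(pos * Ts) / np.sum(Ts)) / body_mass


def sprint_power(
    kin: FieldKinematics,
    trunk_pitch: np.ndarray,
    model: RollingResistanceModel,
    m_total: float,
    body_mass: float,
) -> tuple[list[PushCycle], float]:
    """Segment the sprint window into cycles and compute mean power.

    Returns the cycles (with per-cycle power filled in) and the
    mass-normalized weighted mean power [W/kg].
    """
    f_roll = F_roll_series(model, np.asarray(trunk_pitch, dtype=float), m_total)
    cycles = detect_cycles(kin.v_lin, kin.fs, kin.start_idx, kin.end_idx)
    for c in cycles:
        c.po = cycle_power(c, kin.t, kin.v_lin, f_roll, m_total)
    return cycles, mean_field_power(cycles, body_mass)
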