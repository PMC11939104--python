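"""Parameter containers for the wheelchair-athlete forward simulator.

The simulator models the combined athlete + sports-wheelchair system as a
point mass driven by hand-rim push bursts and braked by rolling
resistance.  Rolling resistance is split between the small front castors
(coefficient ``mu_front``) and the large rear wheels (``mu_rear``); the
fraction of weight on the castors follows trunk pitch through an affine,
clamped mapping ``f(theta) = clip(front_load_base +
front_load_per_deg * theta, 0, 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import InvalidParameterError

#: gravitational acceleration [m/s^2]
G = 9.81

#: lateral separation of the rear wheels [m], used only to give the two
#: wheel gyroscopes distinct signals while turning
TRACK_WIDTH = 0.60

COURSE_KINDS = ("sprint", "illinois", "spider", "coastdown")


@dataclass(frozen=True)
class CourseSpec:
    """Geometry and posture schedule of one test.

    Parameters
    ----------
    kind:
        One of ``sprint``, ``illinois``, ``spider``, ``coastdown``.
    waypoints:
        ``(x, y)`` positions in metres.  The chair starts at the first
        waypoint facing the second.  Illinois/Spider courses must end on
        (or behind) the start line so the zero-line end rule fires.
    posture_schedule:
        ``(t [s], trunk pitch [deg])`` breakpoints, linearly interpolated
        and held at the ends.  For coast-down courses the schedule holds
        exactly two entries: the upright pitch and the forward-bent pitch.
    v_max, accel, yaw_rate_max:
        Speed cap [m/s], acceleration [m/s^2] and yaw-rate cap [deg/s]
        used by the waypoint follower for Illinois/Spider courses.
    """

    kind: str
    waypoints: tuple[tuple[float, float], ...] = ()
    posture_schedule: tuple[tuple[float, float], ...] = ((0.0, 10.0),)
    v_max: float = 3.0
    accel: float = 2.0
    yaw_rate_max: float = 240.0

    def __post_init__(self) -> None:
        if self.kind not in COURSE_KINDS:
            raise InvalidParameterError(f"unknown course kind {self.kind!r}")
        if self.v_max <= 0 or self.accel <= 0 or self.yaw_rate_max <= 0:
            raise InvalidParameterError("v_max, accel and yaw_rate_max must be > 0")
        if not self.posture_schedule:
            raise InvalidParameterError("posture_schedule may not be empty")


def sprint_course(pitch_start: float = 5.0, pitch_end: float = 25.0) -> CourseSpec:
    """Straight 10 m sprint; the athlete leans progressively forward."""
    return CourseSpec(
        kind="sprint",
        waypoints=((0.0, 0.0), (10.0, 0.0)),
        posture_schedule=((0.0, pitch_start), (2.0, pitch_end)),
    )


def illinois_course() -> CourseSpec:
    """Out, across, and back through the start line (approximate layout;
    exact court dimensions are configurable, not fixed)."""
    return CourseSpec(
        kind="illinois",
        waypoints=((0.0, 0.0), (10.0, 0.0), (10.0, 3.3), (-0.5, 3.3)),
        posture_schedule=((0.0, 15.0),),
    )


def spider_course() -> CourseSpec:
    """Star of out-and-back runs from the start point, ending across the
    start line."""
    return CourseSpec(
        kind="spider",
        waypoints=(
            (0.0, 0.0),
            (4.0, 0.0),
            (0.0, 0.0),
            (3.0, 3.0),
            (0.0, 0.0),
            (3.0, -3.0),
            (-0.5, 0.0),
        ),
        posture_schedule=((0.0, 15.0),),
    )


def coastdown_course(upright_pitch: float = 0.0, forward_pitch: float = 45.0) -> CourseSpec:
    """Coast-down posture pair: two upright trials then two forward-bent."""
    return CourseSpec(
        kind="coastdown",
        posture_schedule=((0.0, upright_pitch), (1.0, forward_pitch)),
    )


@dataclass(frozen=True)
class SimulationParams:
    """Physical and measurement parameters of one simulated session.

    Defaults describe an adult wheelchair-tennis setup: 70 kg athlete in a
    12 kg sports chair, 0.33 m rear wheels at 18 degrees camber, gym-court
    castor resistance 0.02 with hard-court rear-wheel resistance 0.008.
    """

    body_mass: float = 70.0          # kg
    chair_mass: float = 12.0         # kg
    wheel_radius: float = 0.33       # m
    camber: float = 18.0             # deg
    mu_front: float = 0.02           # castor rolling-resistance coefficient
    mu_rear: float = 0.008           # rear-wheel rolling-resistance coefficient
    front_load_base: float = 0.30    # castor load fraction at 0 deg trunk pitch
    front_load_per_deg: float = 0.30 / 45.0  # fraction per degree of pitch
    push_peak_force: float = 280.0   # N, peak of the half-sine push burst
    push_duration: float = 0.28      # s
    cycle_period: float = 0.85       # s
    n_pushes: int = 12
    course: CourseSpec = field(default_factory=sprint_course)
    gyro_noise_sd: float = 1.0       # deg/s, i.i.d. on every gyro channel
    erg_sample_rate: float = 100.0   # Hz
    imu_sample_rate: float = 200.0   # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.chair_mass <= 0:
            raise InvalidParameterError("masses must be > 0")
        if self.wheel_radius <= 0:
            raise InvalidParameterError("wheel_radius must be > 0")
        if not 0.0 <= self.front_load_base <= 1.0:
            raise InvalidParameterError("front_load_base must lie in [0, 1]")
        if self.mu_front < 0 or self.mu_rear < 0:
            raise InvalidParameterError("rolling-resistance coefficients must be >= 0")
        if self.erg_sample_rate <= 0 or self.imu_sample_rate <= 0:
            raise InvalidParameterError("sample rates must be > 0")
        if self.push_duration <= 0 or self.cycle_period <= 0:
            raise InvalidParameterError("push timing must be > 0")
        if self.push_duration >= self.cycle_period:
            raise InvalidParameterError("push_duration must be < cycle_period")
        if self.n_pushes < 0:
            raise InvalidParameterError("n_pushes must be >= 0")
        if self.gyro_noise_sd < 0:
            raise InvalidParameterError("gyro_noise_sd must be >= 0")
        if abs(self.camber) >= 45.0:
            raise InvalidParameterError("|camber| must be < 45 deg")

    @property
    def m_total(self) -> float:
        """Combined athlete + chair mass [kg]."""
        return self.body_mass + self.chair_mass

    @property
    def wheel_circumference(self) -> float:
        """Rear-wheel circumference WC [m]."""
        return 2.0 * math.pi * self.wheel_radius

    def with_course(self, course: CourseSpec) -> "SimulationParams":
        return replace(self, course=course)
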