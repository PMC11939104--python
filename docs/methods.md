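# Methods

## Scope and data flow

`wheelperf` implements the analysis chain used to characterize wheelchair
court-sport performance from two measurement modalities:

1. **Lab**: a dual-roller ergometer records per-side rim torque `M` [Nm]
   and wheel velocity `v_w` [m/s] at 100 Hz during a 10 m sprint and a
   30 s Wingate effort.
2. **Field**: four 3-axis gyroscopes (both wheel hubs, frame, chest) at
   200 Hz during a 10 m Sprint, an Illinois agility test and a Spider
   maneuverability test, plus a four-trial coast-down protocol used to
   identify rolling resistance.

Because no raw athlete recordings ship with the package, a forward
simulator generates both modalities from a known physical model, and all
pipeline stages are validated by parameter recovery against that ground
truth.

## Models

### Lab power

Per side, instantaneous power is `PO = M / r_w * v_w`.  The sprint
outcome `PO_mean` [W/kg] is the time average of summed-side power from
the start rule (side-averaged velocity > 0.1 m/s) to the first sample at
which mean cumulative wheel distance reaches 10 m, divided by body mass;
`v_peak` is the highest side-averaged velocity sample in that window.
Wingate `P30` [W/kg] averages summed power over 30 s from the start
rule.  Lab channels are filtered with a zero-phase 4th-order 10 Hz
low-pass Butterworth; zero-phase filtering preserves peak timing, which
`v_peak` depends on.  The Wingate braking resistance is an input of the
protocol, not something this package computes.

### Field kinematics

Wheel-hub gyroscopes are mounted on a cambered axle, so frame yaw leaks
into the spin-axis reading.  The corrected angular wheel velocity is

    v_ang = GyroY_wheel + sin(camber) * GyroZ_frame   [deg/s]
    v_lin = WC / 360 * v_ang                          [m/s]

with `WC` the wheel circumference.  Yaw rate `v_rot` is the frame Z
gyroscope.  Field channels are filtered with a recursive (causal
single-pass) 2nd-order 10 Hz Butterworth; the filter mode is
configurable (`causal`, `zero_phase`, `none`) because the causal default
adds ~20 ms of group delay that matters when checking noise-free
identities but is part of the realistic processing path.

Timing rules: every trial starts when side-averaged `v_lin` first
exceeds 0.1 m/s.  The sprint ends when the mean of both wheels'
cumulative distances reaches 10 m (the crossing sample is included).
Illinois/Spider trials end at the last re-crossing of the zero line (the
line through the start point perpendicular to the initial heading,
evaluated on the dead-reckoned position), ignoring crossings within 2 s
of the start so launch wobble cannot end a trial.  Dead reckoning
integrates yaw rate into heading and velocity along it (trapezoid rule).
Peak rotational velocity is reported as an absolute value, making it
invariant to turn direction.

### Coast-down rolling resistance

During free deceleration the equation of motion is
`dv/dt = -F_roll / m_total` with

    F_roll = g * m_total * [ f(theta) * mu_front + (1 - f(theta)) * mu_rear ]

where `f(theta) = clip(front_load_base + front_load_per_deg * theta, 0, 1)`
maps trunk pitch `theta` to the front-castor load fraction.  Defaults
`f(0 deg) = 0.30`, `f(45 deg) = 0.60` are a configurable model choice, not a
claim about any particular load-distribution measurement.  Each trial's
deceleration is the least-squares slope of `v(t)` over the coast window
(velocity-slope fitting has lower variance than position-curvature at
~2 s windows); the window starts 0.3 s after the last
positive-acceleration episode (detected on a 0.31 s moving average with
edge padding, shifted back by half the smoothing window) and spans the
longest tolerantly-monotone-decreasing stretch above a 0.02 m/s
standstill floor, requiring at least 1.5 s and a real net deceleration.
With at least one trial per posture, the two coefficients are solved by
least squares; negative solutions are clipped to zero with a warning,
never silently accepted.  Air resistance is neglected throughout, and no
velocity-dependent friction terms are modeled.

### Field sprint power

For straight-line sprinting (no rotation, flat floor, negligible air
resistance), per-cycle mechanical power is

    po = (1/T) * [ ∫ F_roll(t) v_lin(t) dt + 1/2 m_total (v_end² - v_start²) ]

with `F_roll(t)` evaluated from the coast-down model at the measured
chest pitch (trunk-inclination correction).  The kinetic-energy term is
divided by `T` together with the loss integral — the only dimensionally
consistent reading (units of W).  Cycles are segmented at local minima
of filtered `v_lin` (>= 0.3 s apart, prominence >= 0.05 m/s); when no
minima exist the whole window is one cycle (logged).  Because the
kinetic terms telescope and the loss integrals add, the time-weighted
mean over cycles that tile the window equals the single-window power
exactly, so the reported `PO_mean` is insensitive to segmentation
details — the tests assert this identity at 1e-9 relative.  Power is
computed for the sprint only; turning power involves unknown rotational
inertia and slip and is out of scope.

### Statistics

Group comparison uses the Student (pooled-variance) independent t test —
identified by the df = n1 + n2 − 2 convention — at a Bonferroni-corrected
alpha (0.05 / number of tests; 11 outcomes gives 0.0045).  Outcomes
measured in both environments are compared with a paired t test on
complete pairs.  Associations are fit by ordinary least squares, linear
and quadratic; "curvilinear" is implemented as a quadratic polynomial,
and the quadratic is reported only when its R² beats the linear fit by
more than 0.01 (a nested model's R² can never be lower, so a margin is
required).  Missing values are dropped pairwise per outcome.  When
several attempts of a field test exist, the one with the fastest end
time is analyzed (ties keep the first).

## The simulator

Straight-line trials integrate `m_total dv/dt = F_push(t) - F_roll(t)`
where `F_push` is a train of half-sine bursts (peak `push_peak_force`,
width `push_duration`, period `cycle_period`) — simple, smooth, and
producing the intra-push velocity ripple cycle detection needs.  Both
forces are velocity independent, so the ODE is a quadrature; it is
integrated by a cumulative Simpson rule on a fixed 1 kHz grid (midpoint
force evaluations included) with explicit clamping at standstill, which
is exact for this model class and bit-reproducible.  Agility courses
follow waypoints with trapezoidal speed profiles on straights and
turn-in-place segments at a bounded yaw rate; phase boundaries snap to
the 5 ms grid (common multiple of the 1 kHz internal and 200 Hz IMU
steps) so trapezoidal heading integration is exact at phase boundaries
at both rates.  Exact Illinois/Spider court dimensions are deliberately
configurable; the defaults approximate the out-across-back and
star-shaped layouts.

Sensor rendering inverts the camber correction (`GyroY = (360/WC) v_side
- sin(camber) GyroZ`), gives the two wheels differential speeds
`v ∓ (track/2) ω` with a fixed 0.60 m track (needed only so the wheel
channels differ while turning), and adds i.i.d. Gaussian noise
(default SD 1 deg/s) to every gyro channel.  No bias, drift,
accelerometer or magnetometer channels are modeled; chest pitch is
rendered noise-free.  The ergometer renders each hand's share of the
push force as rim torque at 100 Hz, noise-free.

Default physical parameters describe an adult wheelchair-tennis setup:
70 kg athlete, 12 kg chair, 0.33 m wheels at 18° camber, castor
coefficient 0.02 with rear-wheel coefficient 0.008 (hard-court class
values), pushes of 280 N peak / 0.28 s width / 0.85 s period.  These
land mid-cohort on the published outcome scales (sprint `PO_mean`
≈ 1.6 W/kg, `v_peak` ≈ 3.6 m/s, 10 m in ≈ 5.4 s).

The cohort generator draws a latent ability per player (elite mean
shifted by `effect` SD, default 2), renders 11 lab/field outcomes as
affine transforms of ability plus noise, and sets symmetric noise
variances so the population R² of any field outcome on any lab outcome
equals `assoc_r2` (default 0.85) exactly in the linear case; a
`curvilinear` flag adds a mild quadratic ability component.  Durations
are rendered with negative sign (better ability, faster time).

**What passing tests do and do not show.**  The simulator shares the
pipeline's structural assumptions (velocity-independent rolling
resistance, affine load shifting, perfect sensor synchronization, white
gyro noise).  Recovery results therefore validate the implementation
and the identifiability of the protocol, not robustness to bias/drift,
wheel slip, desynchronization or model misspecification in real
recordings.

## Numerical choices and tolerances

- Integration: cumulative Simpson at 1 kHz internal; trapezoid rule for
  all distance/energy integrals; sensors rendered by linear
  interpolation onto their sample grids.
- Start/end indices are inclusive of the crossing sample.
- Coast segmentation tolerances: 2e-4 m/s per-sample slack for
  monotonicity, 0.2 m/s² push-episode threshold, 0.02 m/s standstill
  floor, mean-slope floor 0.01 m/s².
- Zero pooled variance in t tests: t = 0 for equal means, an explicit
  infinite-t flag otherwise (never NaN).
- Degenerate inputs raise typed exceptions (`errors.py`) rather than
  returning sentinel values.

## Monte-Carlo problem sizes

The test suite uses 200 seeded coast-down protocols, 100 seeded noisy
sprints, 2,000 null cohorts and 5,000 association replicates.  The
acceptance script reports the same quantities at 60 / 40 / 800 / 2,000
replicates, sizes at which every Monte-Carlo estimate is stable to well
inside its acceptance margin.

## Known limitations

- Rolling resistance is velocity independent; bearing friction and air
  drag are not modeled, so simulated Wingate plateaus are governed by
  impulse balance rather than drag equilibrium.
- Power estimation covers straight-line sprints only.
- The zero-line end rule is evaluated on position (not cumulated
  distance); a trial that drifts sideways across the line would end even
  without backward travel.
- Gyroscope bias/drift handling and sensor fusion are out of scope; the
  IMU streams are assumed synchronized on one clock.
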