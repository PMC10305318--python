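# Methods

This note documents the models, the numeric choices, and what the synthetic
experiments do and do not demonstrate.

## Signal model and units

Canonical units are physical: seconds, g, deg/s, µT, Pa. Logs recorded in
raw sensor counts are converted on read with the device scale factors
(accelerometer 512 LSB/g, gyroscope 32.8 LSB/°/s, magnetometer 3.3 LSB/µT,
barometer 6 LSB/Pa); the conversion is linear and invertible, and both unit
systems are accepted because embedded firmware may log either. Validation
enforces strictly increasing timestamps, the ±4 g accelerometer range, the
300–1100 hPa barometer range, and a median sampling interval within 10% of
the declared rate (100 Hz default).

Device frame: +X the wearer's right, +Y superior, +Z anterior. At upright
stance the accelerometer reads +1 g on +Y. This mounting is a modelling
choice (the hardware convention is not observable from the outside); it is
what makes the fall-direction sign rules fall out naturally: right lean →
roll > 0, forward lean → pitch > 0.

## Orientation: gradient-descent fusion

The orientation filter is the standard gradient-descent (Madgwick) design:
the quaternion rate from gyro integration is corrected by β times the
normalized gradient of the gravity-alignment objective. β defaults to 0.1,
the usual operating regime at 100 Hz — larger values track faster but pass
more accelerometer noise into the angles. With a magnetometer present the
objective gains a magnetic-field alignment term (reference field taken as
the measured field rotated to earth and flattened to horizontal+vertical,
absorbing declination); that gradient is evaluated by central differences,
which is exact to O(ε²) and acceptable because the magnetometer path is not
performance-critical — the accelerometer-only path, which runs per sample,
uses the closed-form Jacobian.

The filter state is initialized from the first accelerometer sample
(shortest rotation aligning predicted gravity with the measurement). From a
deliberately wrong initial quaternion the β-bounded correction would need
tens of seconds to pull in a 90° error, which is exactly why the protocol
has the wearer walk for ~3 s after putting the device on before the state
machine engages.

Lean angles are computed from the predicted up-direction in the body frame,
`roll = atan2(−ux, √(uy²+uz²))`, `pitch = atan2(−uz, √(ux²+uy²))`, which is
stable near the lying posture (a plain Euler extraction degenerates there).
A separate aerospace Z-Y-X conversion is provided for interoperability;
pitch is clamped at the gimbal boundary.

## Altitude: hypsometric conversion + scalar Kalman filter

Relative altitude is `44330·(1 − (p/p_ref)^0.190263)` against a reference
pressure averaged over the first 0.5 s of the trace (≈ +1 m per −12 Pa near
sea level). The barometer is noisy (~±1 m), so a scalar random-walk Kalman
filter smooths the altitude: process noise q = 1e-4 m² per 10 ms step,
measurement noise r = 0.01 m². The steady-state gain is ≈0.095, i.e. a
~0.1 s time constant: fast enough to track a 0.5 s chest drop inside the
1.5 s observation window, slow enough to cut the noise std by ~4.6×. The
windowed pressure difference ΔP is evaluated on the smoothed altitude
mapped back through the inverse hypsometric formula; on the raw channel the
6 Pa sensor noise alone would saturate the 3 Pa threshold.

## Feature frames and windows

Decisions are made every 0.1 s (the device's read cadence). ΔP uses the
fixed 1.5 s observation window. The window for ΔG is not prescribed
anywhere, so 1.0 s was chosen: long enough to contain both the weightless
dip and the impact peak of one fall (≤ 0.5 s apart), short enough that slow
activities cannot accumulate a spurious range. ΔG is the max−min of the
resultant G in the window — a range statistic sees the dip and the peak in
a single number.

## Behavior state machine

Eight states; inputs are per-tick candidate labels classified from the
feature frames with a fixed priority (FALLING > LYING > SITTING_DOWN /
STANDING_UP > WALKING > quiescent STANDING) so exactly one label emerges
per frame. Classification thresholds (config-exposed, defaults):

* lying: max(|roll|, |pitch|) > 60° sustained for 1 s;
* sitting down / standing up: |Δaltitude| over the 1.5 s window inside the
  chair band 0.25–0.7 m, with matching sign, debounced over 3 consecutive
  ticks (barometric noise occasionally grazes the band edge);
* walking: ≥ 3 step peaks above 1.15 g in a trailing 2 s window with a
  median cadence near 1.5–2.5 Hz;
* initialization: sustained walking for 3 s (≈ ten steps) to leave INITIAL.

The transition table is the explicit legality gate: unlisted (state, input)
pairs are no-ops, self-inputs are no-ops, and FALLING is reachable from
every active state. SITTING_DOWN and STANDING_UP are transient; they
resolve to SITTING/STANDING once the input has been quiescent for the 1 s
dwell, which is when the completion action (`sit_down`, `stand_up`) is
emitted. The exact edge set of the original controller is not recoverable,
so the shipped table is a faithful reconstruction of the described
behaviors and is loadable/editable as CSV.

## Fall rule, direction, impact

The rule is a strict conjunction evaluated every tick: ΔG > 600 counts and
ΔP > 3 Pa. The G threshold is interpreted in raw accelerometer counts
(600/512 ≈ 1.17 g) and the pressure threshold in Pa (≈ 0.25 m) — with the
device's scale factors these are the only physically plausible readings of
the bare numbers, and both are configurable. A 3 s refractory period
prevents bounce peaks from double-counting. Direction is classified from
the lean angles 0.5 s after the impact peak (the settled lying posture,
which the experiment figures use as the discriminator), with a 20° dead
zone below which the direction is flagged indeterminate. Impact magnitude
is the maximum resultant G between the weightless minimum (first dip below
0.6 g) and 1 s after it; with no dip the whole-window peak is returned and
flagged.

## Alert verification

Pure timer logic with injected time and a pluggable notifier: a fall opens
a PENDING alert (first notification) with a 30 s deadline; cancel is valid
strictly before the deadline; at the deadline the alert is CONFIRMED and
escalated iff the current behavior state is FALLING or LYING — a fallen
person who has not gotten up is lying, so "still down" is read from the
state machine rather than from a raw re-detection. Each fall therefore
produces exactly one or two notifications. Notifier failures queue the
action without losing the record.

## Synthetic trials

Each trial is a kinematic script of segments (stance, walk, sit-down,
sit, stand-up, deliberate lie-down, fall) rendered into four mutually
consistent channels: the G profile, the lean trajectory, the chest height,
and pressure via the inverse hypsometric formula, plus seeded Gaussian
sensor noise (acc σ 0.01 g, gyro σ 0.5 deg/s, pressure σ 6 Pa ≈ the
barometer's ±1 m accuracy). Gyro rates are the analytic derivatives of the
lean trajectory, so the orientation filter sees consistent inertial data.
Fall segments draw per-trial magnitudes from plausible ranges: weightless
dip 0.25–0.45 g, impact peak 2.2–3.6 g, settled lean 70–85° with signs
encoding the direction, chest drop to lying height (standing chest height
1.15–1.35 m; chair drop 0.40–0.50 m). Every protocol begins with ~4.5 s of
walking, which doubles as FSM initialization, exactly as the wear-in
procedure prescribes.

Category scripts: A — walk, sit down, sit, fall from the chair;
B — walk, brief stance, fall from standing; C — walk, sit down, begin
standing up (+0.30 m), fall mid-rise. Matched negatives per category use
the confusable activities: sit-down (also a quick 0.8 s variant) for A,
long walks and deliberate lying down for B, full sit/stand cycles for C.

What the simulator does **not** model: multi-axis tumbling falls, soft or
staged falls with near-threshold signatures, recovery steps after impact,
sensor saturation/clipping beyond a hard ±4 g clip, barometric drift and
weather trends, and inter-subject variability beyond the parameter ranges
above. Perfect scores on this grid therefore demonstrate internal
consistency of the pipeline under the stated signal model — that the
thresholds, windows and state logic interlock correctly — not field
performance on real elderly falls, which only a human-subject study can
establish.

## Numerical details and degenerate inputs

Quaternions are renormalized every step (norm drift < 1e-9 over 1e5
updates). Zero-norm accelerometer samples degrade to gyro-only integration
for that step, flagged. Non-finite altitude measurements skip the Kalman
update. Traces shorter than the 1.5 s window emit frames flagged truncated.
Metrics with zero denominators are reported as absent, never as zero.
Direction ties (|roll| = |pitch|) resolve to the pitch axis. Scoring
matches a predicted event to a true fall within 2 s; extra events are false
positives.

## Problem sizes

The shipped experiment uses 50 trials per category × direction cell
(600 falls + 600 matched negatives, ~15 s of 100 Hz data each), which makes
the three headline metrics stable to well under a percentage point and
completes in tens of seconds on one CPU; `--n-per-cell` scales it.
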