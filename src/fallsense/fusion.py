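"""Sensor fusion: resultant G, orientation, and filtered barometric altitude.

Turns a raw 100 Hz trace into the three feature streams the behavior state
machine and the fall rule consume:

* the resultant G value ``sqrt(ax^2 + ay^2 + az^2)``;
* roll/pitch lean angles from a gradient-descent (Madgwick) orientation
  filter that fuses gyroscope integration with an accelerometer (and, when a
  magnetometer is present, magnetic field) correction scaled by the gain β;
* relative altitude from the hypsometric conversion of barometric pressure,
  smoothed by a scalar Kalman filter, with the pressure difference observed
  over a trailing 1.5 s window.

Device frame convention: +X is the wearer's right, +Y superior (up along the
torso), +Z anterior (out of the chest).  At upright stance the accelerometer
reads +1 g on +Y.  Lean-angle signs follow the fall-direction rule: a forward
lean gives positive pitch, a right lean positive roll.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .config import FusionConfig, STANDARD_PRESSURE_PA
from .signal_io import ImuSample, SensorLog

logger = logging.getLogger(__name__)

# Hypsometric constants (ISA sea-level atmosphere).
_HYPSO_SCALE_M = 44_330.0
_HYPSO_EXP = 0.190263


# ---------------------------------------------------------------------------
# Resultant G
# ---------------------------------------------------------------------------

def g_value(acc) -> float:
    """Euclidean norm of a 3-axis acceleration, in the same unit as the input.

    At rest this is ~1 g; it dips toward 0 during the weightless phase of a
    fall and spikes at ground impact.
    """
    a = np.asarray(acc, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite acceleration component")
    return float(np.linalg.norm(a))


# ---------------------------------------------------------------------------
# Quaternion helpers (scalar-first w,x,y,z; q maps sensor frame to earth frame)
# ---------------------------------------------------------------------------

def quat_normalize(q):
    w, x, y, z = q
    n = math.sqrt(w * w + x * x + y * y + z * z)
    return (w / n, x / n, y / n, z / n)


def quat_multiply(a, b):
    aw, ax, ay, az = a
    bw, bx, by, bz = b
    return (
        aw * bw - ax * bx - ay * by - az * bz,
        aw * bx + ax * bw + ay * bz - az * by,
        aw * by - ax * bz + ay * bw + az * bx,
        aw * bz + ax * by - ay * bx + az * bw,
    )


def up_in_body(q) -> tuple[float, float, float]:
    """Direction of 'up' (the specific-force direction at rest) in the sensor
    frame, as predicted by the orientation quaternion."""
    w, x, y, z = q
    return (
        2.0 * (x * z - w * y),
        2.0 * (w * x + y * z),
        w * w - x * x - y * y + z * z,
    )


def quat_from_two_vectors(v_from, v_to):
    """Shortest-arc quaternion rotating ``v_from`` onto ``v_to``."""
    f = np.asarray(v_from, float)
    f = f / np.linalg.norm(f)
    t = np.asarray(v_to, float)
    t = t / np.linalg.norm(t)
    d = float(np.dot(f, t))
    if d < -1.0 + 1e-12:
        # 180 degrees: pick any axis orthogonal to f
        axis = np.cross(f, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-6:
            axis = np.cross(f, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        return (0.0, float(axis[0]), float(axis[1]), float(axis[2]))
    c = np.cross(f, t)
    return quat_normalize((1.0 + d, float(c[0]), float(c[1]), float(c[2])))


def quaternion_to_euler(q) -> tuple[float, float, float]:
    """Aerospace Z-Y-X Euler angles (roll, pitch, yaw) in degrees.

    Pitch is clamped at the gimbal boundary (|pitch| -> 90 deg).
    """
    w, x, y, z = quat_normalize(q)
    sinp = 2.0 * (w * y - z * x)
    if abs(sinp) > 1.0 - 1e-12:
        logger.debug("gimbal proximity: |pitch| clamped to 90 deg")
        sinp = math.copysign(1.0, sinp)
    roll = math.atan2(2.0 * (w * x + y * z), 1.0 - 2.0 * (x * x + y * y))
    pitch = math.asin(sinp)
    yaw = math.atan2(2.0 * (w * z + x * y), 1.0 - 2.0 * (y * y + z * z))
    return (math.degrees(roll), math.degrees(pitch), math.degrees(yaw))


def euler_to_quaternion(roll_deg: float, pitch_deg: float, yaw_deg: float):
    """Inverse of :func:`quaternion_to_euler` (intrinsic Z-Y-X composition)."""
    r = math.radians(roll_deg) / 2.0
    p = math.radians(pitch_deg) / 2.0
    y = math.radians(yaw_deg) / 2.0
    qx = (math.cos(r), math.sin(r), 0.0, 0.0)
    qy = (math.cos(p), 0.0, math.sin(p), 0.0)
    qz = (math.cos(y), 0.0, 0.0, math.sin(y))
    return quat_normalize(quat_multiply(quat_multiply(qz, qy), qx))


def lean_angles(q) -> tuple[float, float]:
    """(roll, pitch) lean of the chest-worn device in degrees.

    Computed from the predicted up direction in the body frame, so the signs
    follow the fall-direction convention: right lean -> roll > 0, forward
    lean -> pitch > 0.  Both angles live in [-90, 90].
    """
    ux, uy, uz = up_in_body(q)
    roll = math.degrees(math.atan2(-ux, math.hypot(uy, uz)))
    pitch = math.degrees(math.atan2(-uz, math.hypot(ux, uy)))
    return (roll, pitch)


# ---------------------------------------------------------------------------
# Madgwick gradient-descent orientation filter
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OrientationState:
    """Unit quaternion plus derived angles.

    ``roll``/``pitch`` are the chest lean angles (fall-direction sign
    convention); ``yaw`` is the aerospace heading angle.  ``beta`` is the
    gradient-descent gain trading gyro trust against accelerometer trust.
    """

    q: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.0)
    roll: float = 0.0
    pitch: float = 0.0
    yaw: float = 0.0
    beta: float = 0.1
    gyro_only: bool = False   # set when a step had to skip the accel correction

    @classmethod
    def from_accel(cls, acc, beta: float = 0.1) -> "OrientationState":
        """Initial orientation aligning the predicted gravity direction with
        a static accelerometer reading."""
        q = quat_from_two_vectors(acc, (0.0, 0.0, 1.0))
        r, p = lean_angles(q)
        return cls(q=q, roll=r, pitch=p, yaw=quaternion_to_euler(q)[2], beta=beta)


def _madgwick_imu_step(q, gx, gy, gz, ax, ay, az, beta, dt):
    """One published gradient-descent IMU update.  Gyro in rad/s; returns
    (quaternion, used_accel)."""
    q0, q1, q2, q3 = q
    # quaternion rate from gyroscope
    qd0 = 0.5 * (-q1 * gx - q2 * gy - q3 * gz)
    qd1 = 0.5 * (q0 * gx + q2 * gz - q3 * gy)
    qd2 = 0.5 * (q0 * gy - q1 * gz + q3 * gx)
    qd3 = 0.5 * (q0 * gz + q1 * gy - q2 * gx)
    norm_a = math.sqrt(ax * ax + ay * ay + az * az)
    used_accel = norm_a > 1e-12
    if used_accel and beta > 0.0:
        ax, ay, az = ax / norm_a, ay / norm_a, az / norm_a
        # objective: predicted gravity direction minus measured
        f1 = 2.0 * (q1 * q3 - q0 * q2) - ax
        f2 = 2.0 * (q0 * q1 + q2 * q3) - ay
        f3 = 2.0 * (0.5 - q1 * q1 - q2 * q2) - az
        # J^T f
        s0 = -2.0 * q2 * f1 + 2.0 * q1 * f2
        s1 = 2.0 * q3 * f1 + 2.0 * q0 * f2 - 4.0 * q1 * f3
        s2 = -2.0 * q0 * f1 + 2.0 * q3 * f2 - 4.0 * q2 * f3
        s3 = 2.0 * q1 * f1 + 2.0 * q2 * f2
        norm_s = math.sqrt(s0 * s0 + s1 * s1 + s2 * s2 + s3 * s3)
        if norm_s > 1e-12:
            qd0 -= beta * s0 / norm_s
            qd1 -= beta * s1 / norm_s
            qd2 -= beta * s2 / norm_s
            qd3 -= beta * s3 / norm_s
    q0 += qd0 * dt
    q1 += qd1 * dt
    q2 += qd2 * dt
    q3 += qd3 * dt
    n = math.sqrt(q0 * q0 + q1 * q1 + q2 * q2 + q3 * q3)
    return (q0 / n, q1 / n, q2 / n, q3 / n), used_accel


def _rotate_to_body(q, d):
    """Rotate an earth-frame vector into the body frame (q* x d x q)."""
    w, x, y, z = q
    dx, dy, dz = d
    # v = R(q)^T d, expanded
    return (
        (w * w + x * x - y * y - z * z) * dx + 2.0 * (x * y + w * z) * dy + 2.0 * (x * z - w * y) * dz,
        2.0 * (x * y - w * z) * dx + (w * w - x * x + y * y - z * z) * dy + 2.0 * (y * z + w * x) * dz,
        2.0 * (x * z + w * y) * dx + 2.0 * (y * z - w * x) * dy + (w * w - x * x - y * y + z * z) * dz,
    )


def _marg_objective(q, a_hat, m_hat, b):
    """Stacked gravity + magnetic-field alignment residual (6-vector)."""
    pg = _rotate_to_body(q, (0.0, 0.0, 1.0))
    pb = _rotate_to_body(q, b)
    return np.array(
        [pg[0] - a_hat[0], pg[1] - a_hat[1], pg[2] - a_hat[2],
         pb[0] - m_hat[0], pb[1] - m_hat[1], pb[2] - m_hat[2]]
    )


def _madgwick_marg_step(q, gx, gy, gz, ax, ay, az, mx, my, mz, beta, dt):
    """MARG update: gyro integration minus the β-scaled normalized gradient of
    the joint gravity/field objective (gradient evaluated by central
    differences; this path is not performance critical)."""
    q0, q1, q2, q3 = q
    qd = [
        0.5 * (-q1 * gx - q2 * gy - q3 * gz),
        0.5 * (q0 * gx + q2 * gz - q3 * gy),
        0.5 * (q0 * gy - q1 * gz + q3 * gx),
        0.5 * (q0 * gz + q1 * gy - q2 * gx),
    ]
    na = math.sqrt(ax * ax + ay * ay + az * az)
    nm = math.sqrt(mx * mx + my * my + mz * mz)
    used_accel = na > 1e-12 and nm > 1e-12
    if used_accel and beta > 0.0:
        a_hat = (ax / na, ay / na, az / na)
        m_hat = (mx / nm, my / nm, mz / nm)
        # reference field: measured field rotated to earth, flattened to
        # (horizontal, 0, vertical) to absorb unknown declination
        h = _rotate_to_body((q0, -q1, -q2, -q3), m_hat)  # body->earth
        b = (math.hypot(h[0], h[1]), 0.0, h[2])
        grad = np.zeros(4)
        eps = 1e-6
        for i in range(4):
            qp = list(q)
            qp[i] += eps
            qm = list(q)
            qm[i] -= eps
            fp = _marg_objective(tuple(qp), a_hat, m_hat, b)
            fm = _marg_objective(tuple(qm), a_hat, m_hat, b)
            grad[i] = (fp @ fp - fm @ fm) / (4.0 * eps)  # d(1/2|f|^2)/dq_i
        ng = float(np.linalg.norm(grad))
        if ng > 1e-12:
            for i in range(4):
                qd[i] -= beta * grad[i] / ng
    q_new = (q0 + qd[0] * dt, q1 + qd[1] * dt, q2 + qd[2] * dt, q3 + qd[3] * dt)
    return quat_normalize(q_new), used_accel


def madgwick_update(state: OrientationState, sample: ImuSample, dt: float) -> OrientationState:
    """Advance the orientation one step from an IMU sample.

    Uses the MARG variant when the sample carries a magnetometer reading,
    otherwise the accelerometer-only update.  A zero-norm accelerometer
    vector degrades to pure gyro integration for that step (flagged on the
    returned state).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    gx, gy, gz = (math.radians(v) for v in np.asarray(sample.gyro, float))
    ax, ay, az = np.asarray(sample.acc, float)
    if sample.mag is not None:
        mx, my, mz = np.asarray(sample.mag, float)
        q, used = _madgwick_marg_step(
            state.q, gx, gy, gz, ax, ay, az, mx, my, mz, state.beta, dt
        )
    else:
        q, used = _madgwick_imu_step(state.q, gx, gy, gz, ax, ay, az, state.beta, dt)
    if not used:
        logger.debug("zero-norm accelerometer at t=%.3f: gyro-only step", sample.t)
    r, p = lean_angles(q)
    return OrientationState(
        q=q, roll=r, pitch=p, yaw=quaternion_to_euler(q)[2],
        beta=state.beta, gyro_only=not used,
    )


# ---------------------------------------------------------------------------
# Barometric altitude
# ---------------------------------------------------------------------------

def pressure_to_altitude(p: float, p_ref: float) -> float:
    """Hypsometric relative altitude (m) of pressure ``p`` against ``p_ref``.

    Near sea level ~12 Pa of pressure drop corresponds to +1 m.
    """
    for value in (p, p_ref):
        v = np.asarray(value, float)
        if np.any(v < 30_000.0) or np.any(v > 110_000.0):
            raise ValueError(f"pressure {value!r} outside barometer operating range")
    return _HYPSO_SCALE_M * (1.0 - (np.asarray(p, float) / p_ref) ** _HYPSO_EXP)


def altitude_to_pressure(h: float, p_ref: float) -> float:
    """Inverse hypsometric conversion: pressure at relative altitude ``h``."""
    return p_ref * (1.0 - np.asarray(h, float) / _HYPSO_SCALE_M) ** (1.0 / _HYPSO_EXP)


@dataclass(frozen=True)
class AltitudeState:
    """Scalar Kalman state for the relative altitude."""

    altitude: float = 0.0
    variance: float = 1.0       # m^2
    p_ref: float = STANDARD_PRESSURE_PA
    q_proc: float = 1e-4        # process noise per step, m^2
    r_meas: float = 0.01        # measurement noise, m^2 (~±1 m barometer)


def kalman_altitude_update(state: AltitudeState, z: float) -> AltitudeState:
    """One predict/update step on an altitude measurement ``z`` (m).

    The posterior estimate is a convex combination of the prior and the
    measurement; non-finite measurements skip the step.
    """
    if not math.isfinite(z):
        logger.debug("non-finite altitude measurement skipped")
        return state
    p_prior = state.variance + state.q_proc
    k = p_prior / (p_prior + state.r_meas)
    return replace(
        state,
        altitude=state.altitude + k * (z - state.altitude),
        variance=(1.0 - k) * p_prior,
    )


# ---------------------------------------------------------------------------
# Feature frames
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureFrame:
    """One decision-tick snapshot of the fused feature streams."""

    t: float
    g_value: float        # g
    roll: float           # deg, right lean positive
    pitch: float          # deg, forward lean positive
    yaw: float            # deg
    altitude: float       # m relative to the trace reference
    dp_window: float      # Pa, |pressure change| over the trailing 1.5 s
    dg_window: float      # g, max-min resultant G over the trailing window
    truncated: bool = False   # trailing window did not fully fit the trace


def compute_features(log: SensorLog, config: FusionConfig | None = None) -> list[FeatureFrame]:
    """Run the full fusion stack over a trace, one frame per decision tick.

    The orientation filter and altitude Kalman filter run at the native
    sample rate; frames are emitted every ``decision_tick_s`` (0.1 s default).
    ``dp_window`` is the absolute pressure change across the trailing 1.5 s,
    evaluated on the Kalman-smoothed altitude mapped back to pressure;
    ``dg_window`` is the max-min resultant G over the trailing window.
    """
    cfg = config or FusionConfig()
    n = len(log)
    if n == 0:
        return []
    t = log.t
    g = np.linalg.norm(log.acc, axis=1)

    # --- orientation at full rate ---
    state = OrientationState.from_accel(log.acc[0], beta=cfg.beta)
    q = state.q
    beta = cfg.beta
    quats = np.empty((n, 4))
    quats[0] = q
    dts = np.diff(t)
    acc = log.acc
    gyro_rad = np.radians(log.gyro)
    use_marg = log.mag is not None
    for i in range(1, n):
        if use_marg:
            m = log.mag[i]
            q, _ = _madgwick_marg_step(
                q, gyro_rad[i, 0], gyro_rad[i, 1], gyro_rad[i, 2],
                acc[i, 0], acc[i, 1], acc[i, 2], m[0], m[1], m[2],
                beta, dts[i - 1],
            )
        else:
            q, _ = _madgwick_imu_step(
                q, gyro_rad[i, 0], gyro_rad[i, 1], gyro_rad[i, 2],
                acc[i, 0], acc[i, 1], acc[i, 2], beta, dts[i - 1],
            )
        quats[i] = q

    # --- altitude at full rate ---
    n_ref = max(1, min(n, int(round(cfg.p_ref_window_s * log.rate_hz))))
    p_ref = float(np.mean(log.pressure[:n_ref]))
    alt_meas = pressure_to_altitude(log.pressure, p_ref)
    alt_state = AltitudeState(
        altitude=float(alt_meas[0]), variance=cfg.kalman_r_m2,
        p_ref=p_ref, q_proc=cfg.kalman_q_m2, r_meas=cfg.kalman_r_m2,
    )
    alt_f = np.empty(n)
    alt_f[0] = alt_state.altitude
    for i in range(1, n):
        alt_state = kalman_altitude_update(alt_state, float(alt_meas[i]))
        alt_f[i] = alt_state.altitude
    p_smooth = altitude_to_pressure(alt_f, p_ref)

    # --- trailing windows at full rate (uniform-rate rolling) ---
    w_g = max(1, int(round(cfg.dg_window_s * log.rate_hz)))
    gs = pd.Series(g)
    dg_all = (gs.rolling(w_g, min_periods=1).max() - gs.rolling(w_g, min_periods=1).min()).to_numpy()

    # --- decision ticks ---
    stride = max(1, int(round(cfg.decision_tick_s * log.rate_hz)))
    frames: list[FeatureFrame] = []
    short_trace = (t[-1] - t[0]) < cfg.dp_window_s
    if short_trace:
        logger.warning("trace shorter than the %.1f s window: frames truncated", cfg.dp_window_s)
    for i in range(0, n, stride):
        t_i = float(t[i])
        j = int(np.searchsorted(t, t_i - cfg.dp_window_s, side="left"))
        truncated = (t_i - t[0]) < cfg.dp_window_s
        dp = abs(float(p_smooth[i] - p_smooth[j]))
        roll, pitch = lean_angles(quats[i])
        frames.append(
            FeatureFrame(
                t=t_i,
                g_value=float(g[i]),
                roll=roll,
                pitch=pitch,
                yaw=quaternion_to_euler(quats[i])[2],
                altitude=float(alt_f[i]),
                dp_window=dp,
                dg_window=float(dg_all[i]),
                truncated=truncated,
            )
        )
    return frames


def write_feature_frames(frames: list[FeatureFrame], path) -> None:
    """Export frames in the package CSV dialect."""
    df = pd.DataFrame(
        {
            "t": [f.t for f in frames],
            "g_value": [f.g_value for f in frames],
            "roll": [f.roll for f in frames],
            "pitch": [f.pitch for f in frames],
            "yaw": [f.yaw for f in frames],
            "altitude": [f.altitude for f in frames],
            "dp_window": [f.dp_window for f in frames],
            "dg_window": [f.dg_window for f in frames],
        }
    )
    df.to_csv(path, index=False, float_format="%.9g")
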