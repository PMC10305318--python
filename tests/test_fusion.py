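"""Fusion layer: resultant G, orientation filter, altitude, feature frames."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fallsense import (
    AltitudeState,
    ImuSample,
    OrientationState,
    SensorLog,
    compute_features,
    euler_to_quaternion,
    g_value,
    kalman_altitude_update,
    lean_angles,
    madgwick_update,
    pressure_to_altitude,
    altitude_to_pressure,
    quaternion_to_euler,
)
from fallsense.config import FusionConfig, STANDARD_PRESSURE_PA
from fallsense.fusion import _madgwick_imu_step

from conftest import make_still_log


def _sample(acc, gyro=(0.0, 0.0, 0.0), mag=None, t=0.0):
    return ImuSample(t=t, acc=np.asarray(acc, float), gyro=np.asarray(gyro, float),
                     pressure=STANDARD_PRESSURE_PA,
                     mag=None if mag is None else np.asarray(mag, float))


class TestGValue:
    @pytest.mark.parametrize(
        "acc,expected",
        [((0, 0, 512), 512.0), ((3, 4, 0), 5.0), ((300, 400, 1200), 1300.0)],
    )
    def test_known_norms(self, acc, expected):
        assert g_value(acc) == pytest.approx(expected)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            g_value((np.nan, 0, 1))

    @given(
        acc=st.tuples(*[st.floats(-4, 4) for _ in range(3)]),
        perm=st.permutations([0, 1, 2]),
        signs=st.tuples(*[st.sampled_from([-1.0, 1.0]) for _ in range(3)]),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_invariant_under_axis_permutation_and_sign(self, acc, perm, signs):
        a = np.asarray(acc)
        b = np.array([acc[perm[i]] * signs[i] for i in range(3)])
        assert g_value(b) == pytest.approx(g_value(a), abs=1e-12)


class TestMadgwick:
    def test_gravity_aligned_equilibrium(self):
        state = OrientationState(beta=0.1)
        s = _sample((0.0, 0.0, 1.0))
        for _ in range(500):
            state = madgwick_update(state, s, 0.01)
        roll, pitch, _ = quaternion_to_euler(state.q)
        assert abs(roll) < 0.5 and abs(pitch) < 0.5

    def test_accelerometer_tilt_convergence_30deg(self):
        state = OrientationState(beta=0.1)
        s = _sample((0.0, math.sin(math.radians(30)), math.cos(math.radians(30))))
        for _ in range(2000):
            state = madgwick_update(state, s, 0.01)
        roll, _, _ = quaternion_to_euler(state.q)
        assert roll == pytest.approx(30.0, abs=0.5)

    def test_pure_gyro_integration_90_degrees(self):
        """90 deg/s about Y for 1 s with the accel correction disabled."""
        state = OrientationState(beta=0.0)
        s = _sample((0.0, 0.0, 1.0), gyro=(0.0, 90.0, 0.0))
        for _ in range(100):
            state = madgwick_update(state, s, 0.01)
        _, pitch, _ = quaternion_to_euler(state.q)
        assert pitch == pytest.approx(90.0, abs=1.0)

    @pytest.mark.parametrize("tilt_deg", range(-60, 61, 15))
    def test_static_tilt_recovery_sweep(self, tilt_deg):
        """Converged lean matches the accelerometer closed form within 0.5 deg."""
        th = math.radians(tilt_deg)
        state = OrientationState(beta=0.1)
        s = _sample((0.0, math.sin(th), math.cos(th)))
        for _ in range(3000):
            state = madgwick_update(state, s, 0.01)
        roll, _, _ = quaternion_to_euler(state.q)
        assert roll == pytest.approx(tilt_deg, abs=0.5)

    def test_quaternion_norm_preserved_over_1e5_updates(self):
        rng = np.random.default_rng(1)
        q = (1.0, 0.0, 0.0, 0.0)
        worst = 0.0
        for _ in range(100_000):
            g = rng.normal(0, 1, 3)
            a = rng.normal(0, 0.3, 3) + [0, 0, 1]
            q, _ = _madgwick_imu_step(q, g[0], g[1], g[2], a[0], a[1], a[2], 0.1, 0.01)
            worst = max(worst, abs(math.sqrt(sum(c * c for c in q)) - 1.0))
        assert worst < 1e-9

    def test_zero_accel_degrades_to_gyro_only(self):
        state = OrientationState(beta=0.1)
        out = madgwick_update(state, _sample((0.0, 0.0, 0.0), gyro=(10.0, 0, 0)), 0.01)
        assert out.gyro_only

    def test_marg_equilibrium_with_magnetometer(self):
        state = OrientationState(beta=0.1)
        s = _sample((0, 0, 1.0), mag=(22.0, 0.0, -40.0))
        for _ in range(200):
            state = madgwick_update(state, s, 0.01)
        roll, pitch, _ = quaternion_to_euler(state.q)
        assert abs(roll) < 1.0 and abs(pitch) < 1.0

    def test_invalid_dt_rejected(self):
        with pytest.raises(ValueError):
            madgwick_update(OrientationState(), _sample((0, 0, 1)), 0.0)


class TestEulerConversion:
    def test_identity(self):
        assert quaternion_to_euler((1, 0, 0, 0)) == pytest.approx((0, 0, 0))

    def test_axis_aligned_roll(self):
        q = euler_to_quaternion(90.0, 0.0, 0.0)
        roll, pitch, yaw = quaternion_to_euler(q)
        assert roll == pytest.approx(90.0, abs=1e-6)
        assert abs(pitch) < 1e-6 and abs(yaw) < 1e-6

    @given(
        roll=st.floats(-179, 179),
        pitch=st.floats(-85, 85),   # away from gimbal lock
        yaw=st.floats(-179, 179),
    )
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_round_trip(self, roll, pitch, yaw):
        r2, p2, y2 = quaternion_to_euler(euler_to_quaternion(roll, pitch, yaw))
        assert r2 == pytest.approx(roll, abs=1e-6)
        assert p2 == pytest.approx(pitch, abs=1e-6)
        assert y2 == pytest.approx(yaw, abs=1e-6)

    def test_lean_angle_sign_conventions(self):
        """Forward lean -> pitch > 0; right lean -> roll > 0 (upright = +Y up)."""
        upright = OrientationState.from_accel((0.0, 1.0, 0.0))
        assert lean_angles(upright.q) == pytest.approx((0.0, 0.0), abs=1e-9)
        # leaning forward 30 deg: up-vector tips toward -Z (anterior faces down)
        fwd = OrientationState.from_accel(
            (0.0, math.cos(math.radians(30)), -math.sin(math.radians(30)))
        )
        assert fwd.pitch == pytest.approx(30.0, abs=1e-6)
        right = OrientationState.from_accel(
            (-math.sin(math.radians(30)), math.cos(math.radians(30)), 0.0)
        )
        assert right.roll == pytest.approx(30.0, abs=1e-6)


class TestAltitude:
    def test_reference_pressure_maps_to_zero(self):
        assert pressure_to_altitude(101_325.0, 101_325.0) == 0.0

    def test_twelve_pascal_drop_is_about_one_meter(self):
        h = pressure_to_altitude(101_313.0, 101_325.0)
        assert h == pytest.approx(1.0, abs=0.02)
        assert pressure_to_altitude(101_337.0, 101_325.0) == pytest.approx(-1.0, abs=0.02)

    def test_inverse_conversion_round_trip(self):
        p = altitude_to_pressure(pressure_to_altitude(100_900.0, 101_325.0), 101_325.0)
        assert p == pytest.approx(100_900.0, rel=1e-9)

    def test_out_of_range_pressure_rejected(self):
        with pytest.raises(ValueError):
            pressure_to_altitude(20_000.0, 101_325.0)


class TestKalman:
    def test_constant_zero_is_a_fixed_point(self):
        state = AltitudeState(altitude=0.0, variance=0.01)
        for _ in range(50):
            state = kalman_altitude_update(state, 0.0)
        assert state.altitude == 0.0

    def test_step_response_is_monotone_toward_measurement(self):
        state = AltitudeState(altitude=0.0, variance=0.01)
        estimates = []
        for _ in range(100):
            state = kalman_altitude_update(state, 1.0)
            estimates.append(state.altitude)
        assert all(b >= a for a, b in zip(estimates, estimates[1:]))
        assert 0 < estimates[0] < 1 and estimates[-1] < 1

    def test_noisy_convergence_within_steady_state_band(self):
        """200 noisy measurements around 0.5 m land within 3x the closed-form
        steady-state output sigma."""
        q, r = 1e-4, 0.01
        p_ss = (-q + math.sqrt(q * q + 4 * q * r)) / 2.0
        k_ss = (p_ss + q) / (p_ss + q + r)
        sigma_meas = 0.1
        sigma_out = sigma_meas * math.sqrt(k_ss / (2 - k_ss))
        rng = np.random.default_rng(7)
        state = AltitudeState(altitude=0.0, variance=r, q_proc=q, r_meas=r)
        for z in 0.5 + rng.normal(0, sigma_meas, 200):
            state = kalman_altitude_update(state, float(z))
        assert state.altitude == pytest.approx(0.5, abs=3 * sigma_out)

    def test_non_finite_measurement_skips_step(self):
        state = AltitudeState(altitude=0.3, variance=0.005)
        out = kalman_altitude_update(state, float("nan"))
        assert out == state

    @given(prior=st.floats(-5, 5), z=st.floats(-5, 5), var=st.floats(1e-6, 1.0))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_estimate_is_convex_combination(self, prior, z, var):
        state = AltitudeState(altitude=prior, variance=var)
        out = kalman_altitude_update(state, z)
        lo, hi = min(prior, z), max(prior, z)
        assert lo - 1e-12 <= out.altitude <= hi + 1e-12


class TestComputeFeatures:
    def test_still_trace_features(self, still_log):
        frames = compute_features(still_log)
        assert len(frames) == 100  # 10 s at 0.1 s ticks
        for f in frames:
            assert f.g_value == pytest.approx(1.0, abs=1e-9)
            assert f.dg_window == pytest.approx(0.0, abs=1e-9)
            assert f.dp_window == pytest.approx(0.0, abs=1e-6)
            assert abs(f.roll) < 0.5 and abs(f.pitch) < 0.5

    def test_pressure_step_appears_in_dp_window(self):
        log = make_still_log(10.0)
        log.pressure[log.t >= 5.0] -= 15.0
        frames = compute_features(log)
        dp = {round(f.t, 2): f.dp_window for f in frames}
        in_window = [v for t, v in dp.items() if 5.0 <= t <= 6.5]
        assert max(in_window) > 12.0
        assert max(dp.values()) < 15.5
        before = [v for t, v in dp.items() if 3.0 <= t < 5.0]
        assert max(before) < 1.0

    def test_truncated_frames_flagged_at_trace_start(self, still_log):
        frames = compute_features(still_log)
        assert frames[0].truncated
        assert not frames[-1].truncated

    def test_empty_log_gives_no_frames(self):
        log = SensorLog(t=np.empty(0), acc=np.empty((0, 3)),
                        gyro=np.empty((0, 3)), pressure=np.empty(0))
        assert compute_features(log) == []
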