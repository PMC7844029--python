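"""IMU calibration, pitch/roll recovery, LED-derived variables, angular
differencing, and spike/behavior synchronization."""

import numpy as np
import pytest

from splinelnp.kinematics import (
    AccelStream,
    bin_spikes,
    calibrate_imu,
    compute_angular_velocities,
    compute_led_variables,
    compute_pitch_roll,
    synchronize_and_bin,
)
from splinelnp.simulate import simulate_accelerometer


def _static_stream(a_vec, n=60, rate=30.0):
    return AccelStream(np.arange(n) / rate, np.tile(a_vec, (n, 1)))


class TestCalibration:
    def test_flat_orientation_gives_identity(self):
        calib = calibrate_imu(_static_stream([0.0, 0.0, 1.0]))
        assert calib.theta_r == 0.0 and calib.theta_p == 0.0
        np.testing.assert_allclose(calib.R, np.eye(3), atol=1e-12)

    def test_pure_roll_closed_form(self):
        phi = 0.3
        calib = calibrate_imu(
            _static_stream([0.0, np.sin(phi), np.cos(phi)]))
        assert calib.theta_r == pytest.approx(phi, abs=1e-12)
        assert calib.theta_p == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("theta_r, theta_p",
                             [(0.4, -0.3), (-0.7, 0.2), (1.1, 0.9)])
    def test_rotation_orthonormal_and_maps_calib_to_vertical(
            self, theta_r, theta_p):
        rec = simulate_accelerometer([10.0], [5.0],
                                     calib_orientation=(theta_r, theta_p))
        calib = calibrate_imu(rec.calibration)
        R = calib.R
        np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-10)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-10)
        rotated = R @ calib.a_calib
        np.testing.assert_allclose(
            rotated / np.linalg.norm(rotated), [0, 0, 1], atol=1e-9)

    def test_near_zero_gravity_rejected(self):
        with pytest.raises(ValueError, match="0.5 g"):
            calibrate_imu(_static_stream([0.0, 0.0, 0.1]))

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="1 s"):
            calibrate_imu(_static_stream([0.0, 0.0, 1.0], n=10))


class TestPitchRollRecovery:
    def test_head_fixed_posture_reads_zero(self):
        rec = simulate_accelerometer([0.0], [0.0],
                                     calib_orientation=(0.5, -0.4))
        calib = calibrate_imu(rec.calibration)
        pitch, roll, ok = compute_pitch_roll(rec.stream, calib)
        assert ok.all()
        np.testing.assert_allclose(pitch, 0.0, atol=1e-9)
        np.testing.assert_allclose(roll, 0.0, atol=1e-9)

    def test_round_trip_identity_on_grid(self):
        """Forward accelerometer model then recovery is the identity
        within 1e-6 degrees over (+/-50 deg)^2."""
        grid = np.linspace(-50, 50, 9)
        pp, rr = np.meshgrid(grid, grid)
        rec = simulate_accelerometer(pp.ravel(), rr.ravel(),
                                     calib_orientation=(0.3, 0.2))
        calib = calibrate_imu(rec.calibration)
        pitch, roll, ok = compute_pitch_roll(rec.stream, calib)
        assert ok.all()
        np.testing.assert_allclose(pitch, pp.ravel(), atol=1e-6)
        np.testing.assert_allclose(roll, rr.ravel(), atol=1e-6)

    def test_static_noisy_stream_sd_below_one_degree(self):
        n = 30 * 60 * 10  # 10 minutes at 30 Hz
        rec = simulate_accelerometer(np.zeros(n), np.zeros(n),
                                     noise_sd=0.01, seed=3)
        calib = calibrate_imu(rec.calibration)
        pitch, roll, _ = compute_pitch_roll(rec.stream, calib)
        assert pitch.std() < 1.0 and roll.std() < 1.0

    def test_small_drift_keeps_recovered_angles_within_one_degree(self):
        n = 30 * 600
        rec = simulate_accelerometer(
            np.zeros(n), np.zeros(n),
            drift_per_s=np.array([1e-5, -1e-5, 0.0]), seed=4)
        calib = calibrate_imu(rec.calibration)
        pitch, roll, _ = compute_pitch_roll(rec.stream, calib)
        assert np.abs(pitch).max() < 1.0 and np.abs(roll).max() < 1.0

    def test_gimbal_adjacent_inputs_rejected(self):
        with pytest.raises(ValueError, match="90"):
            simulate_accelerometer([92.0], [0.0])


class TestLedVariables:
    def test_midpoint(self):
        pos, _, _, _ = compute_led_variables(
            np.array([[0.0, 0.0]]), np.array([[0.0, 2.0]]))
        np.testing.assert_allclose(pos[0], [0.0, 1.0])

    def test_azimuth_atan2_convention(self):
        """LED difference along +y reads 90 deg (counterclockwise from +x)."""
        _, _, ha, _ = compute_led_variables(
            np.array([[0.0, 1.0]]), np.array([[0.0, 0.0]]))
        assert ha[0] == pytest.approx(90.0)

    def test_stationary_leds_zero_speed(self):
        led = np.tile([5.0, 5.0], (50, 1))
        _, speed, _, _ = compute_led_variables(led, led + [0.0, 2.0])
        np.testing.assert_allclose(speed, 0.0)

    def test_missing_led_samples_masked(self):
        led1 = np.array([[0.0, 0.0], [np.nan, 1.0], [2.0, 2.0]])
        led2 = led1 + 1.0
        _, _, _, valid = compute_led_variables(led1, led2)
        np.testing.assert_array_equal(valid, [True, False, True])


class TestAngularVelocity:
    def test_wrap_gives_short_arc(self):
        """A step from 359 deg to 1 deg is +100 deg/s at 50 Hz."""
        v = compute_angular_velocities(np.array([359.0, 1.0]), dt=0.02)
        assert v[1] == pytest.approx(100.0)

    def test_constant_angle_zero(self):
        v = compute_angular_velocities(np.full(100, 123.0), dt=0.02)
        np.testing.assert_allclose(v, 0.0)

    def test_linear_ramp_recovered(self):
        t = np.arange(500) * 0.02
        v = compute_angular_velocities(10.0 * t, dt=0.02, circular=False)
        np.testing.assert_allclose(v, 10.0, atol=1e-9)

    def test_circular_velocity_bounded(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(0, 360, 1000)
        v = compute_angular_velocities(angles, dt=0.02)
        assert np.all(np.abs(v) * 0.02 <= 180.0 + 1e-9)


class TestSynchronizeAndBin:
    def test_half_open_binning(self):
        """A spike at t = 0.030 s lands in bin 1 of [0.02, 0.04)."""
        counts = bin_spikes(np.array([0.030]), 0.0, 5)
        np.testing.assert_array_equal(counts, [0, 1, 0, 0, 0])

    def test_spike_count_conservation(self):
        rng = np.random.default_rng(1)
        events = np.sort(rng.uniform(0.0, 10.0, 400))
        counts = bin_spikes(events, 0.0, 500)
        assert counts.sum() == 400

    def test_ramp_interpolation_exact_and_full_session(self):
        n30, dur = 300, 10.0
        t30 = np.arange(n30) / 30.0
        ramp = 3.0 * t30
        a = np.column_stack([
            -np.tan(np.radians(ramp)), np.zeros(n30), np.ones(n30)])
        a /= np.linalg.norm(a, axis=1, keepdims=True)
        stream = AccelStream(t30, a, pulse_times=t30[::30])
        from splinelnp.kinematics import ImuCalibration
        calib = ImuCalibration(np.array([0.0, 0, 1.0]), 0.0, 0.0, np.eye(3))
        t50 = np.arange(int(dur * 50)) * 0.02
        led1 = np.column_stack([t50, np.zeros_like(t50)])
        session, spikes = synchronize_and_bin(
            stream, calib, t50, led1, led1 + [0.0, 1.0],
            {"c0": np.array([0.030, 5.01])},
            led_pulses=t30[::30],
        )
        # 30 Hz linear pitch ramp interpolates exactly onto the 50 Hz clock
        inside = t50 <= t30[-1]
        np.testing.assert_allclose(session.channels["H_p"][inside],
                                   3.0 * t50[inside], atol=1e-9)
        assert spikes.counts.sum() == 2

    def test_unmatched_pulse_counts_fail(self):
        t30 = np.arange(90) / 30.0
        stream = AccelStream(t30, np.tile([0.0, 0, 1.0], (90, 1)),
                             pulse_times=t30[::30])
        from splinelnp.kinematics import ImuCalibration
        calib = ImuCalibration(np.array([0.0, 0, 1.0]), 0.0, 0.0, np.eye(3))
        t50 = np.arange(100) * 0.02
        led = np.zeros((100, 2))
        with pytest.raises(ValueError, match="sync failure"):
            synchronize_and_bin(stream, calib, t50, led, led + [0, 1],
                                {}, led_pulses=t50[:5])
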