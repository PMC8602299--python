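"""Magnetometer calibration, rest handling, and the complementary filter."""

import numpy as np
import pytest

from wristkin import rotations as rot
from wristkin.errors import IllConditionedFitError, InsufficientRestError
from wristkin.imu import (
    FilterConfig,
    ImuStream,
    MagCalibration,
    apply_mag_calibration,
    calibrate_magnetometer,
    estimate_gyro_bias,
    fuse_orientation,
    prepend_rest,
    run_imu_pipeline,
)

RATE = 100.0


def static_stream(n=1000, q_true=None, accel=None, mag=None):
    t = np.arange(n) / RATE
    if q_true is not None:
        accel = rot.rotate_vector(rot.conjugate(q_true), [0.0, 0.0, 9.81])
        mag = rot.rotate_vector(rot.conjugate(q_true), [30.0, 0.0, -40.0])
    return ImuStream(
        t=t,
        gyro=np.zeros((n, 3)),
        accel=np.tile(accel, (n, 1)),
        mag=np.tile(mag, (n, 1)),
        sample_rate=RATE,
    )


def sphere_points(rng, n=300, radius=50.0):
    v = rng.normal(size=(n, 3))
    return radius * v / np.linalg.norm(v, axis=1, keepdims=True)


class TestMagCalibration:
    def test_hard_iron_recovery(self, rng):
        h = np.array([10.0, -5.0, 3.0])
        cal = calibrate_magnetometer(sphere_points(rng) + h)
        assert np.linalg.norm(cal.hard_iron - h) < 0.5
        assert np.allclose(cal.soft_iron, np.eye(3), atol=1e-6)

    def test_centered_sphere_gives_identity(self, rng):
        cal = calibrate_magnetometer(sphere_points(rng))
        assert np.linalg.norm(cal.hard_iron) < 1e-6
        assert np.allclose(cal.soft_iron, np.eye(3), atol=1e-9)

    def test_soft_iron_recovery_reduces_norm_spread(self, rng):
        S = np.array([[1.08, 0.03, 0.0], [0.03, 0.95, 0.02], [0.0, 0.02, 0.98]])
        S = S / np.linalg.det(S) ** (1 / 3)
        raw = sphere_points(rng) @ S.T + np.array([4.0, 2.0, -7.0])
        cal = calibrate_magnetometer(raw)
        fixed = cal.apply(raw)

        def cv(x):
            nn = np.linalg.norm(x - x.mean(axis=0) * 0, axis=1)
            return np.std(nn) / np.mean(nn)

        raw_centered = raw - raw.mean(axis=0)
        assert cv(fixed) < 0.01
        assert cv(fixed) < cv(raw_centered)

    def test_coplanar_cloud_rejected(self, rng):
        pts = rng.normal(size=(10, 3))
        pts[:, 2] = 0.0
        with pytest.raises(IllConditionedFitError):
            calibrate_magnetometer(pts)

    def test_apply_identity_is_noop(self, rng):
        stream = static_stream(50, q_true=rot.IDENTITY)
        out = apply_mag_calibration(stream, MagCalibration.identity())
        assert np.array_equal(out.mag, stream.mag)
        assert np.array_equal(out.gyro, stream.gyro)

    def test_apply_cancels_offset_exactly(self):
        h = np.array([10.0, -5.0, 3.0])
        cal = MagCalibration(hard_iron=h, soft_iron=np.eye(3))
        stream = static_stream(10, accel=[0, 0, 9.81], mag=h)
        assert np.allclose(apply_mag_calibration(stream, cal).mag, 0.0)

    def test_true_parameter_round_trip(self, rng):
        """Distorting and calibrating with the true parameters recovers directions."""
        S = np.array([[1.05, 0.02, 0.0], [0.02, 0.97, 0.01], [0.0, 0.01, 0.99]])
        S = S / np.linalg.det(S) ** (1 / 3)
        h = np.array([8.0, -3.0, 5.0])
        clean = sphere_points(rng, 100)
        distorted = clean @ S.T + h
        cal = MagCalibration(hard_iron=h, soft_iron=np.linalg.inv(S))
        # inv(S) of a symmetric unit-det matrix is symmetric unit-det
        back = cal.apply(distorted)
        assert np.max(np.abs(back - clean)) < 1e-9


class TestRestHandling:
    def test_gyro_bias_recovered(self, rng):
        stream = static_stream(600, q_true=rot.IDENTITY)
        bias = np.array([0.01, -0.02, 0.005])
        stream = ImuStream(
            t=stream.t,
            gyro=stream.gyro + bias,
            accel=stream.accel,
            mag=stream.mag,
            sample_rate=RATE,
        )
        est = estimate_gyro_bias(stream, (0.0, 5.0))
        assert np.allclose(est, bias, atol=1e-12)

    def test_prepend_noop_when_total_equals_rest(self):
        stream = static_stream(1000, q_true=rot.IDENTITY)
        cfg = FilterConfig(rest_duration=5.0, prepend_total=5.0)
        out, offset = prepend_rest(stream, (0.0, 5.0), cfg)
        assert offset == 0
        assert len(out) == len(stream)

    def test_prepend_tiling_arithmetic(self):
        """5 s rest tiled to 30 s total: 25 s (5 copies) added in front."""
        stream = static_stream(2000, q_true=rot.IDENTITY)
        cfg = FilterConfig(rest_duration=5.0, prepend_total=30.0)
        out, offset = prepend_rest(stream, (0.0, 4.99), cfg)
        assert offset == 5 * 500
        assert len(out) == len(stream) + offset
        assert np.all(np.diff(out.t) > 0)
        assert np.allclose(out.t[offset:], stream.t)

    def test_short_rest_rejected(self):
        stream = static_stream(100, q_true=rot.IDENTITY)
        with pytest.raises(InsufficientRestError):
            prepend_rest(stream, (0.0, 0.3), FilterConfig())

    def test_prepended_filter_converges_before_recording_starts(self):
        """With a deliberately wrong seed, the prepended rest pulls the filter
        onto the static solution by the original t0; unprepended it has not."""
        q_true = rot.from_rotvec([0.4, -0.3, 1.0])
        stream = static_stream(1500, q_true=q_true)
        q_solver = rot.orientation_from_accel_mag(stream.accel[0], stream.mag[0])
        q_bad = rot.compose(q_true, rot.from_axis_angle([1, 0, 0], np.deg2rad(25)))
        cfg = FilterConfig(run_gain=0.05, init_gain=2.5, rest_duration=5.0, prepend_total=30.0)
        padded, offset = prepend_rest(stream, (0.0, 5.0), cfg)
        with_pre = fuse_orientation(padded, cfg, q_bad, prepend_offset=offset)
        without = fuse_orientation(stream, cfg, q_bad, prepend_offset=0)
        err_pre = rot.angle_between(with_pre.q[0], q_solver)
        err_raw = rot.angle_between(without.q[0], q_solver)
        assert err_pre < np.deg2rad(0.1)
        assert err_raw > np.deg2rad(10)


class TestComplementaryFilter:
    def test_static_matches_solver_everywhere(self):
        """Noiseless static stream: every fused sample equals the static solver."""
        q_true = rot.from_rotvec([0.2, 0.5, -0.7])
        stream = static_stream(1000, q_true=q_true)
        q0 = rot.orientation_from_accel_mag(stream.accel[0], stream.mag[0])
        cfg = FilterConfig()
        padded, offset = prepend_rest(stream, (0.0, 5.0), cfg)
        traj = fuse_orientation(padded, cfg, q0, prepend_offset=offset)
        assert len(traj) == len(stream)
        assert float(rot.angle_between(traj.q, q0).max()) < 1e-6

    def test_pure_gyro_matches_fine_integration_oracle(self):
        """run_gain = 0 over a 10 s time-varying rotation profile."""

        def omega(tt):
            return np.stack(
                [0.8 * np.sin(0.7 * tt), 0.5 * np.sin(1.1 * tt + 0.3), 0.3 * np.sin(1.7 * tt)],
                axis=-1,
            )

        t = np.arange(int(10 * RATE)) / RATE
        stream = ImuStream(
            t=t,
            gyro=omega(t),
            accel=np.tile([0, 0, 9.81], (len(t), 1)),
            mag=np.tile([30, 0, -40.0], (len(t), 1)),
            sample_rate=RATE,
        )
        cfg = FilterConfig(run_gain=0.0, init_gain=0.0)
        traj = fuse_orientation(stream, cfg, rot.IDENTITY)

        q = rot.IDENTITY.copy()
        oracle = np.empty((len(t), 4))
        oracle[0] = q
        fine = 50
        for k in range(1, len(t)):
            tt = np.linspace(t[k - 1], t[k], fine + 1)
            mids = omega(0.5 * (tt[:-1] + tt[1:]))
            for m in mids:
                q = rot.compose(q, rot.from_rotvec(m * (tt[1] - tt[0])))
            q = q / np.linalg.norm(q)
            oracle[k] = q
        assert float(rot.angle_between(traj.q, oracle).max()) < 1e-3

    def test_magnetic_step_cannot_tilt_the_estimate(self):
        """A field disturbance step changes only heading when mag_yaw_only."""
        q_true = rot.from_rotvec([0.3, -0.2, 0.9])
        stream = static_stream(1200, q_true=q_true)
        mag2 = stream.mag.copy()
        mag2[600:] += np.array([15.0, -8.0, 5.0])
        disturbed = ImuStream(
            t=stream.t, gyro=stream.gyro, accel=stream.accel, mag=mag2, sample_rate=RATE
        )
        cfg = FilterConfig(run_gain=0.3, init_gain=0.0, mag_yaw_only=True)
        qa = fuse_orientation(stream, cfg, q_true).q
        qb = fuse_orientation(disturbed, cfg, q_true).q
        up = np.array([0.0, 0.0, 1.0])
        ga = rot.rotate_vector(rot.conjugate(qa), up)
        gb = rot.rotate_vector(rot.conjugate(qb), up)
        per_sample = np.linalg.norm(np.diff(gb - ga, axis=0), axis=1)
        assert float(np.linalg.norm(gb - ga, axis=1).max()) < 1e-6
        assert float(per_sample.max()) < 1e-6
        # while heading does drift away
        assert float(rot.angle_between(qb[-1], qa[-1])) > np.deg2rad(1)

    def test_output_unit_norm(self):
        stream = static_stream(500, q_true=rot.from_rotvec([0.1, 0.2, 0.3]))
        traj = run_imu_pipeline(stream, FilterConfig())
        assert np.allclose(np.linalg.norm(traj.q, axis=1), 1.0, atol=1e-9)

    def test_zero_mag_warns_and_skips_heading(self):
        q_true = rot.from_rotvec([0.1, 0.0, 0.5])
        stream = static_stream(200, q_true=q_true)
        mag0 = stream.mag.copy()
        mag0[100:] = 0.0
        s2 = ImuStream(t=stream.t, gyro=stream.gyro, accel=stream.accel, mag=mag0, sample_rate=RATE)
        cfg = FilterConfig(run_gain=0.5, init_gain=0.0)
        with pytest.warns(UserWarning, match="magnetometer"):
            traj = fuse_orientation(s2, cfg, q_true)
        # tilt still tracked exactly
        up_err = rot.rotate_vector(rot.conjugate(traj.q[-1]), [0, 0, 1.0])
        truth = rot.rotate_vector(rot.conjugate(q_true), [0, 0, 1.0])
        assert np.allclose(up_err, truth, atol=1e-9)
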