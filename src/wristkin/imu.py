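"""9-axis IMU sensor fusion: magnetometer calibration, rest-period seeding, and
a yaw-constrained complementary filter.

The pipeline that turns a raw gyro/accel/mag stream into a world-frame
orientation trajectory is:

1. ellipsoid-fit magnetometer calibration (:func:`calibrate_magnetometer`,
   :func:`apply_mag_calibration`) — removes hard-iron offset and soft-iron
   distortion measured by waving the sensor through many orientations;
2. gyro bias removal from a static rest window (:func:`estimate_gyro_bias`);
3. tiling the rest window onto the front of the recording
   (:func:`prepend_rest`) so the filter converges on synthetic static data
   *before* the real recording starts, allowing a low run-time gain;
4. seeding from the static two-vector orientation solver and running the
   complementary filter (:func:`fuse_orientation`).

The filter propagates orientation by gyro integration and corrects it with two
vector error terms: a tilt error from the measured vs. predicted gravity
direction, and a heading error computed from the *horizontal component* of the
magnetometer only and applied as a rotation about the world vertical axis.
Constraining the magnetometer to heading means magnetic disturbances cannot
corrupt the estimated gravity direction.

:func:`run_imu_pipeline` chains all of the above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from . import rotations as rot
from .errors import (
    IllConditionedFitError,
    InsufficientRestError,
    InvalidInputError,
    NoValidDataError,
)

__all__ = [
    "ImuStream",
    "MagCalibration",
    "FilterConfig",
    "OrientationTrajectory",
    "calibrate_magnetometer",
    "apply_mag_calibration",
    "estimate_gyro_bias",
    "prepend_rest",
    "fuse_orientation",
    "run_imu_pipeline",
]


@dataclass
class ImuStream:
    """One sensor's timestamped 9-axis recording.

    Attributes
    ----------
    t : (N,) seconds, strictly increasing.
    gyro : (N, 3) rad/s, sensor frame.
    accel : (N, 3) m/s² specific force, sensor frame (static reading is +g up).
    mag : (N, 3) magnetic field, arbitrary consistent units, sensor frame.
    sample_rate : nominal rate in Hz.
    """

    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        for name in ("gyro", "accel", "mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.t.shape[0], 3):
                raise InvalidInputError(f"{name} must have shape (N, 3) matching t")
            if not np.all(np.isfinite(arr)):
                raise InvalidInputError(f"NaN/inf in {name} channel; gaps must be explicit")
            setattr(self, name, arr)
        if self.t.ndim != 1 or len(self.t) == 0:
            raise InvalidInputError("t must be a non-empty 1-D array")
        if not np.all(np.diff(self.t) > 0):
            raise InvalidInputError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t)

    def window(self, t0: float, t1: float) -> slice:
        """Index slice of samples with t0 <= t <= t1."""
        lo = int(np.searchsorted(self.t, t0, side="left"))
        hi = int(np.searchsorted(self.t, t1, side="right"))
        if hi <= lo:
            raise InvalidInputError(f"window [{t0}, {t1}] contains no samples")
        return slice(lo, hi)


@dataclass
class MagCalibration:
    """Hard/soft-iron magnetometer correction: ``mag' = soft_iron @ (mag - hard_iron)``.

    ``soft_iron`` is symmetric positive definite with unit determinant, so the
    correction restores sphericity without changing the overall field scale.
    """

    hard_iron: np.ndarray
    soft_iron: np.ndarray

    def __post_init__(self) -> None:
        self.hard_iron = np.asarray(self.hard_iron, dtype=float).reshape(3)
        self.soft_iron = np.asarray(self.soft_iron, dtype=float).reshape(3, 3)
        if not np.allclose(self.soft_iron, self.soft_iron.T, atol=1e-9):
            raise InvalidInputError("soft_iron must be symmetric")
        if abs(np.linalg.det(self.soft_iron) - 1.0) > 1e-6:
            raise InvalidInputError("soft_iron must have unit determinant")

    @classmethod
    def identity(cls) -> "MagCalibration":
        return cls(np.zeros(3), np.eye(3))

    def apply(self, mag: np.ndarray) -> np.ndarray:
        return (np.asarray(mag, dtype=float) - self.hard_iron) @ self.soft_iron.T


@dataclass
class FilterConfig:
    """Complementary-filter tuning.

    Attributes
    ----------
    run_gain : 1/s
        Correction gain during the real recording.  Kept low so that transient
        magnetic distortion and reach accelerations distort the estimate as
        little as possible.
    init_gain : 1/s
        Gain used while consuming the synthetic prepended rest; high so the
        estimate locks onto the static solution quickly.
    rest_duration : s
        Length of the static rest window at the start of every recording.
    prepend_total : s
        Total static time (original rest + prepended copies) the filter sees
        before the real recording begins.
    mag_yaw_only : bool
        Restrict the magnetometer to heading corrections (default, recommended).
    accel_norm_bounds : (lo, hi) m/s²
        Tilt correction is skipped for samples whose accelerometer norm falls
        outside these bounds (the sensor is clearly accelerating).
    """

    run_gain: float = 0.1
    init_gain: float = 2.5
    rest_duration: float = 5.0
    prepend_total: float = 30.0
    mag_yaw_only: bool = True
    accel_norm_bounds: tuple[float, float] = (2.0, 20.0)

    def __post_init__(self) -> None:
        if self.run_gain < 0 or self.init_gain < 0:
            raise InvalidInputError("filter gains must be >= 0")
        if self.prepend_total < self.rest_duration:
            raise InvalidInputError("prepend_total must be >= rest_duration")


@dataclass
class OrientationTrajectory:
    """Per-sensor time series of world <- sensor orientations.

    ``valid`` marks samples that carry real information (dropout gaps too long
    to interpolate are left invalid by the pose pipeline).  ``valid is None``
    means all samples are valid.
    """

    t: np.ndarray
    q: np.ndarray
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.t), 4):
            raise InvalidInputError("q must have shape (N, 4) matching t")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.t.shape:
                raise InvalidInputError("valid mask must match t")
            if not self.valid.any():
                raise NoValidDataError("trajectory has no valid samples")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def valid_mask(self) -> np.ndarray:
        return np.ones(len(self.t), dtype=bool) if self.valid is None else self.valid

    def masked_intervals(self) -> list[tuple[float, float]]:
        """Contiguous invalid time intervals as (t_start, t_end) pairs."""
        out: list[tuple[float, float]] = []
        bad = ~self.valid_mask
        i = 0
        n = len(bad)
        while i < n:
            if bad[i]:
                j = i
                while j + 1 < n and bad[j + 1]:
                    j += 1
                out.append((float(self.t[i]), float(self.t[j])))
                i = j + 1
            else:
                i += 1
        return out

    def window(self, t0: float, t1: float) -> slice:
        lo = int(np.searchsorted(self.t, t0, side="left"))
        hi = int(np.searchsorted(self.t, t1, side="right"))
        if hi <= lo:
            raise InvalidInputError(f"window [{t0}, {t1}] contains no samples")
        return slice(lo, hi)


# --------------------------------------------------------------------------
# magnetometer calibration


def calibrate_magnetometer(samples: np.ndarray) -> MagCalibration:
    """Fit hard/soft-iron parameters from magnetometer samples spanning many
    orientations.

    Fits the general quadric ``x' M x + b . x = 1`` by linear least squares,
    recovers the ellipsoid centre (hard iron) and maps the ellipsoid onto a
    sphere with the symmetric square root of ``M``, normalised to unit
    determinant (soft iron).

    Parameters
    ----------
    samples : (N, 3) array, N >= 50 recommended
        Raw magnetometer readings covering a wide spread of directions.

    Raises
    ------
    IllConditionedFitError
        For coplanar or otherwise degenerate sample clouds.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3:
        raise InvalidInputError("samples must be (N, 3)")
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("non-finite magnetometer samples")
    n = x.shape[0]
    if n < 10:
        raise IllConditionedFitError(f"need at least 10 samples, got {n}")

    # scale for conditioning
    scale = float(np.mean(np.linalg.norm(x - x.mean(axis=0), axis=1)))
    if scale == 0:
        raise IllConditionedFitError("all samples identical")
    xs = x / scale

    X, Y, Z = xs[:, 0], xs[:, 1], xs[:, 2]
    D = np.column_stack(
        [X * X, Y * Y, Z * Z, 2 * X * Y, 2 * X * Z, 2 * Y * Z, X, Y, Z]
    )
    sv = np.linalg.svd(D, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-9:
        raise IllConditionedFitError(
            "magnetometer samples are coplanar/degenerate; wave the sensor through more directions"
        )
    p, *_ = np.linalg.lstsq(D, np.ones(n), rcond=None)
    M = np.array(
        [
            [p[0], p[3], p[4]],
            [p[3], p[1], p[5]],
            [p[4], p[5], p[2]],
        ]
    )
    b = p[6:9]
    evals = np.linalg.eigvalsh(M)
    if np.any(evals <= 0):
        raise IllConditionedFitError("fitted quadric is not an ellipsoid")

    center = -0.5 * np.linalg.solve(M, b)
    # symmetric square root of M, then unit determinant
    w, V = np.linalg.eigh(M)
    W = V @ np.diag(np.sqrt(w)) @ V.T
    W = W / np.linalg.det(W) ** (1.0 / 3.0)
    return MagCalibration(hard_iron=center * scale, soft_iron=W)


def apply_mag_calibration(stream: ImuStream, cal: MagCalibration) -> ImuStream:
    """Return a copy of ``stream`` with the magnetometer channel corrected."""
    return replace(stream, mag=cal.apply(stream.mag))


# --------------------------------------------------------------------------
# rest handling


def estimate_gyro_bias(
    stream: ImuStream, rest_window: tuple[float, float], *, rms_warn: float = 0.05
) -> np.ndarray:
    """Mean gyro reading over a static window (rad/s); warns if the window moves."""
    sl = stream.window(*rest_window)
    g = stream.gyro[sl]
    centered_rms = float(np.sqrt(np.mean(np.sum((g - g.mean(axis=0)) ** 2, axis=1))))
    if centered_rms > rms_warn:
        warnings.warn(
            f"gyro RMS {centered_rms:.3f} rad/s in rest window exceeds {rms_warn}; "
            "bias estimate may be contaminated by motion",
            stacklevel=2,
        )
    return g.mean(axis=0)


def prepend_rest(
    stream: ImuStream, rest_window: tuple[float, float], config: FilterConfig
) -> tuple[ImuStream, int]:
    """Tile copies of the rest window onto the front of the recording.

    Copies are added until the total static exposure (prepended copies plus the
    in-recording rest window) reaches ``config.prepend_total`` seconds.
    Timestamps are shifted to stay strictly increasing.  Returns the padded
    stream and the sample offset at which the original recording begins.
    """
    sl = stream.window(*rest_window)
    rest_t = stream.t[sl]
    n_rest = len(rest_t)
    dt = float(np.median(np.diff(stream.t)))
    rest_dur = rest_t[-1] - rest_t[0] + dt
    if rest_dur < 0.5:
        raise InsufficientRestError(
            f"rest window of {rest_dur:.2f} s is shorter than the 0.5 s minimum"
        )
    g = stream.gyro[sl]
    rms = float(np.sqrt(np.mean(np.sum(g**2, axis=1))))
    if rms > 0.05:
        warnings.warn(
            f"rest window gyro RMS {rms:.3f} rad/s > 0.05; limb may not be static",
            stacklevel=2,
        )

    n_tiles = max(0, int(np.ceil((config.prepend_total - rest_dur) / rest_dur - 1e-9)))
    if n_tiles == 0:
        return stream, 0

    gyro = np.concatenate([np.tile(stream.gyro[sl], (n_tiles, 1)), stream.gyro])
    accel = np.concatenate([np.tile(stream.accel[sl], (n_tiles, 1)), stream.accel])
    mag = np.concatenate([np.tile(stream.mag[sl], (n_tiles, 1)), stream.mag])
    offset = n_tiles * n_rest
    t_pre = stream.t[0] + dt * (np.arange(offset) - offset)
    t = np.concatenate([t_pre, stream.t])
    return (
        ImuStream(t=t, gyro=gyro, accel=accel, mag=mag, sample_rate=stream.sample_rate),
        offset,
    )


# --------------------------------------------------------------------------
# complementary filter


def fuse_orientation(
    stream: ImuStream,
    config: FilterConfig,
    q0: np.ndarray,
    *,
    prepend_offset: int = 0,
) -> OrientationTrajectory:
    """Estimate the orientation trajectory with a yaw-constrained
    complementary filter.

    Each step propagates the quaternion by gyro integration (exact quaternion
    exponential over the sample interval) and adds a gain-scaled correction
    built from two vector errors:

    Gyro rates are averaged trapezoidally over each step and integrated with
    the exact quaternion exponential.  The corrections are:

    * tilt: cross product of the measured and predicted gravity directions in
      the sensor frame, skipped when the accelerometer norm is outside
      ``config.accel_norm_bounds``;
    * heading: the angle between the horizontal component of the world-frame
      magnetometer reading and world X, applied as a rotation about the world
      vertical axis (when ``mag_yaw_only``), which by construction cannot
      change the estimated gravity direction.

    ``init_gain`` applies to the first ``prepend_offset`` samples (the tiled
    rest), ``run_gain`` afterwards; the output is trimmed back to the original
    timeline.
    """
    from math import cos, sin, sqrt

    t = stream.t
    n = len(t)
    lo, hi = config.accel_norm_bounds
    # scalar-math inner loop: ~30x faster than small-array numpy at these sizes
    dts = np.diff(t).tolist()
    gyro = stream.gyro.tolist()
    accel = stream.accel.tolist()
    mag = stream.mag.tolist()

    q0 = rot.normalize(np.asarray(q0, dtype=float))
    qw, qx, qy, qz = (float(v) for v in q0)
    out = np.empty((n, 4))
    out[0] = (qw, qx, qy, qz)
    warned_mag = False

    if not config.mag_yaw_only:
        m_ref = rot.rotate_vector(q0, stream.mag[0])
        m_ref = m_ref / np.linalg.norm(m_ref)
        mrx, mry, mrz = (float(v) for v in m_ref)

    for k in range(1, n):
        dt = dts[k - 1]
        gain = config.init_gain if k < prepend_offset else config.run_gain
        # trapezoidal gyro rate over the step (second-order integration)
        g0, g1 = gyro[k - 1], gyro[k]
        wx = 0.5 * (g0[0] + g1[0])
        wy = 0.5 * (g0[1] + g1[1])
        wz = 0.5 * (g0[2] + g1[2])

        if gain > 0.0:
            # third row of R(q): world up expressed in the sensor frame
            ux = 2.0 * (qx * qz - qw * qy)
            uy = 2.0 * (qy * qz + qw * qx)
            uz = 1.0 - 2.0 * (qx * qx + qy * qy)

            ax, ay, az = accel[k]
            an = sqrt(ax * ax + ay * ay + az * az)
            if lo <= an <= hi:
                ax, ay, az = ax / an, ay / an, az / an
                # tilt error: measured x predicted gravity direction
                wx += gain * (ay * uz - az * uy)
                wy += gain * (az * ux - ax * uz)
                wz += gain * (ax * uy - ay * ux)

            mx, my, mz = mag[k]
            mn = sqrt(mx * mx + my * my + mz * mz)
            if mn == 0.0:
                if not warned_mag:
                    warnings.warn(
                        "all-zero magnetometer sample; heading correction skipped",
                        stacklevel=2,
                    )
                    warned_mag = True
            elif config.mag_yaw_only:
                # world-frame field y component (rows of R(q) applied to m)
                mwx = (1.0 - 2.0 * (qy * qy + qz * qz)) * mx + 2.0 * (
                    qx * qy - qw * qz
                ) * my + 2.0 * (qx * qz + qw * qy) * mz
                mwy = 2.0 * (qx * qy + qw * qz) * mx + (
                    1.0 - 2.0 * (qx * qx + qz * qz)
                ) * my + 2.0 * (qy * qz - qw * qx) * mz
                mh = sqrt(mwx * mwx + mwy * mwy)
                if mh > 1e-12 * mn:
                    # yaw error about world vertical, mapped to the sensor
                    # frame: R^T (0, 0, c) = c * (third row of R)
                    c = gain * (-mwy / mh)
                    wx += c * ux
                    wy += c * uy
                    wz += c * uz
            else:
                # full 3-D field correction against the seed's field direction
                px = (1.0 - 2.0 * (qy * qy + qz * qz)) * mrx + 2.0 * (
                    qx * qy + qw * qz
                ) * mry + 2.0 * (qx * qz - qw * qy) * mrz
                py = 2.0 * (qx * qy - qw * qz) * mrx + (
                    1.0 - 2.0 * (qx * qx + qz * qz)
                ) * mry + 2.0 * (qy * qz + qw * qx) * mrz
                pz = 2.0 * (qx * qz + qw * qy) * mrx + 2.0 * (
                    qy * qz - qw * qx
                ) * mry + (1.0 - 2.0 * (qx * qx + qy * qy)) * mrz
                mxn, myn, mzn = mx / mn, my / mn, mz / mn
                wx += gain * (myn * pz - mzn * py)
                wy += gain * (mzn * px - mxn * pz)
                wz += gain * (mxn * py - myn * px)

        # exact quaternion exponential of the corrected rate over dt
        rx, ry, rz = wx * dt, wy * dt, wz * dt
        ang = sqrt(rx * rx + ry * ry + rz * rz)
        if ang > 1e-12:
            half = 0.5 * ang
            s = sin(half) / ang
            ew, ex, ey, ez = cos(half), s * rx, s * ry, s * rz
            qw, qx, qy, qz = (
                qw * ew - qx * ex - qy * ey - qz * ez,
                qw * ex + qx * ew + qy * ez - qz * ey,
                qw * ey - qx * ez + qy * ew + qz * ex,
                qw * ez + qx * ey - qy * ex + qz * ew,
            )
            norm = sqrt(qw * qw + qx * qx + qy * qy + qz * qz)
            qw, qx, qy, qz = qw / norm, qx / norm, qy / norm, qz / norm
        out[k] = (qw, qx, qy, qz)

    return OrientationTrajectory(t=t[prepend_offset:].copy(), q=out[prepend_offset:])


# --------------------------------------------------------------------------
# convenience wrapper


def run_imu_pipeline(
    stream: ImuStream,
    config: FilterConfig | None = None,
    *,
    rest_window: tuple[float, float] | None = None,
    mag_cal: MagCalibration | None = None,
) -> OrientationTrajectory:
    """Full single-sensor pipeline: calibrate, de-bias, prepend rest, seed, fuse.

    ``rest_window`` defaults to the first ``config.rest_duration`` seconds of
    the recording.
    """
    config = config or FilterConfig()
    if rest_window is None:
        rest_window = (float(stream.t[0]), float(stream.t[0]) + config.rest_duration)
    if mag_cal is not None:
        stream = apply_mag_calibration(stream, mag_cal)
    bias = estimate_gyro_bias(stream, rest_window)
    stream = replace(stream, gyro=stream.gyro - bias)
    sl = stream.window(*rest_window)
    q0 = rot.orientation_from_accel_mag(
        stream.accel[sl].mean(axis=0), stream.mag[sl].mean(axis=0)
    )
    padded, offset = prepend_rest(stream, rest_window, config)
    return fuse_orientation(padded, config, q0, prepend_offset=offset)
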