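"""Kinematic metrics derived from a wrist trajectory.

* **EPD** (endpoint distance): |p|, the 3-D shoulder-to-wrist distance.  The
  per-target EPD is the mean over a held reach.
* **AROM** (active range of motion): EPD at the target minus EPD during the
  rest immediately preceding the reach.
* **Sweep area**: shoelace area of the wrist path projected onto the
  horizontal (gravity-orthogonal) plane — a 2-D workspace measure.
* **Endpoint speed (EPS)**: norm of the smooth-noise-robust derivative of p.
* **Smoothness** (normalized mean endpoint speed): max of the EPS peak
  envelope divided by its mean over the movement; 1 for perfectly constant
  speed, 15/8 = 1.875 for a single minimum-jerk stroke.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelmax

from .chain import WristTrajectory
from .errors import (
    InsufficientDataError,
    InvalidInputError,
    SegmentationError,
    TargetLookupError,
    UndefinedMetricError,
)

__all__ = [
    "HoldSegmentation",
    "ReachMetrics",
    "SweepMetrics",
    "epd",
    "segment_holds",
    "segmentation_from_annotations",
    "reach_metrics",
    "delta_between_targets",
    "sweep_area",
    "endpoint_speed",
    "peak_envelope",
    "smoothness",
]

Interval = tuple[float, float]


@dataclass
class HoldSegmentation:
    """Rest and target-hold intervals of a reaching recording.

    ``holds`` is a list of ``(interval, label)`` in temporal order; ``rests``
    lists every detected rest interval (the first is the session-initial
    rest).
    """

    rest_interval: Interval
    holds: list[tuple[Interval, str]]
    rests: list[Interval]

    def __post_init__(self) -> None:
        ivs = [self.rest_interval] + [h[0] for h in self.holds] + list(self.rests)
        for a, b in ivs:
            if b < a:
                raise SegmentationError(f"interval ({a}, {b}) is reversed")
        spans = sorted([h[0] for h in self.holds] + list(self.rests))
        for (a0, b0), (a1, b1) in zip(spans[:-1], spans[1:]):
            if a1 < b0 - 1e-12:
                raise SegmentationError("segmentation intervals overlap")


@dataclass
class ReachMetrics:
    """Per-reach endpoint distance and active range of motion, cm."""

    target: str
    epd_at_target: float
    rest_epd: float

    @property
    def arom(self) -> float:
        return self.epd_at_target - self.rest_epd


@dataclass
class SweepMetrics:
    """Per-sweep horizontal workspace area (cm²) and smoothness (>= 1)."""

    area: float
    smoothness: float
    interval: Interval


def epd(traj: WristTrajectory | np.ndarray) -> np.ndarray:
    """Pointwise endpoint distance |p| in cm."""
    p = traj.p if isinstance(traj, WristTrajectory) else np.asarray(traj, dtype=float)
    return np.linalg.norm(p, axis=-1)


def _stationary_runs(
    t: np.ndarray, series: np.ndarray, speed_threshold: float, min_duration: float
) -> list[tuple[int, int]]:
    """Maximal index runs where |d(series)/dt| < threshold for >= min_duration."""
    v = np.gradient(series, t)
    still = np.abs(v) < speed_threshold
    runs: list[tuple[int, int]] = []
    i = 0
    n = len(t)
    while i < n:
        if still[i]:
            j = i
            while j + 1 < n and still[j + 1]:
                j += 1
            if t[j] - t[i] >= min_duration:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def segment_holds(
    t: np.ndarray,
    epd_series: np.ndarray,
    speed_threshold: float = 2.0,
    min_hold: float = 1.0,
    rest_duration: float | None = None,
) -> HoldSegmentation:
    """Segment an EPD series into the initial rest and the target holds.

    Holds are maximal intervals where |d(EPD)/dt| stays below
    ``speed_threshold`` (cm/s) for at least ``min_hold`` seconds.  The initial
    rest interval is excluded: it is either the first stationary run or, when
    ``rest_duration`` is given, the first that many seconds of the recording.
    Because the reaching task returns to rest between reaches, subsequent
    stationary runs are taken to alternate hold / rest; targets are labelled
    T1, T2, ... in temporal order.  Use
    :func:`segmentation_from_annotations` to override with known intervals.

    Returns an empty segmentation (with a warning) when no holds are found.
    """
    t = np.asarray(t, dtype=float)
    epd_series = np.asarray(epd_series, dtype=float)
    if len(t) < 2 or t[-1] - t[0] < min_hold:
        raise InsufficientDataError("series shorter than min_hold")

    if rest_duration is not None:
        rest_iv: Interval = (float(t[0]), float(t[0] + rest_duration))
        start = float(t[0] + rest_duration)
        sel = t > start
        runs = _stationary_runs(t[sel], epd_series[sel], speed_threshold, min_hold)
        off = int(np.argmax(sel)) if sel.any() else len(t)
        runs = [(i + off, j + off) for i, j in runs]
    else:
        runs = _stationary_runs(t, epd_series, speed_threshold, min_hold)
        if not runs:
            warnings.warn("no stationary intervals found; empty segmentation", stacklevel=2)
            return HoldSegmentation((float(t[0]), float(t[0])), [], [])
        first = runs.pop(0)
        rest_iv = (float(t[first[0]]), float(t[first[1]]))

    holds: list[tuple[Interval, str]] = []
    rests: list[Interval] = [rest_iv]
    for k, (i, j) in enumerate(runs):
        iv = (float(t[i]), float(t[j]))
        if k % 2 == 0:
            holds.append((iv, f"T{len(holds) + 1}"))
        else:
            rests.append(iv)
    if not holds:
        warnings.warn("no holds found after the rest interval", stacklevel=2)
    return HoldSegmentation(rest_iv, holds, rests)


def segmentation_from_annotations(rows: list[tuple[str, float, float]]) -> HoldSegmentation:
    """Build a segmentation from (label, t_start, t_end) annotation rows.

    Rows labelled ``rest`` (case-insensitive) become rest intervals; the first
    rest is the session-initial rest.  All other labels become holds.
    """
    holds: list[tuple[Interval, str]] = []
    rests: list[Interval] = []
    for label, a, b in rows:
        if str(label).strip().lower() == "rest":
            rests.append((float(a), float(b)))
        else:
            holds.append(((float(a), float(b)), str(label)))
    if not rests:
        raise SegmentationError("annotations must include at least one 'rest' interval")
    holds.sort(key=lambda h: h[0][0])
    rests.sort()
    return HoldSegmentation(rests[0], holds, rests)


def reach_metrics(
    t: np.ndarray,
    epd_series: np.ndarray,
    seg: HoldSegmentation,
    *,
    rest_reference: str = "per_reach",
) -> list[ReachMetrics]:
    """Per-reach EPD and AROM from a segmentation.

    ``epd_at_target`` is the mean EPD over the hold; ``rest_epd`` is the mean
    over the rest interval immediately preceding the reach
    (``rest_reference="per_reach"``, default) or over the session-initial rest
    (``rest_reference="session"``).
    """
    if not seg.holds:
        raise InsufficientDataError("segmentation contains no holds")
    if rest_reference not in ("per_reach", "session"):
        raise InvalidInputError(f"unknown rest_reference {rest_reference!r}")
    t = np.asarray(t, dtype=float)
    epd_series = np.asarray(epd_series, dtype=float)

    def interval_mean(iv: Interval) -> float:
        m = (t >= iv[0] - 1e-12) & (t <= iv[1] + 1e-12)
        if not m.any():
            raise SegmentationError(f"interval {iv} contains no samples")
        return float(epd_series[m].mean())

    out: list[ReachMetrics] = []
    for iv, label in seg.holds:
        if rest_reference == "session":
            rest_iv = seg.rest_interval
        else:
            preceding = [r for r in seg.rests if r[1] <= iv[0] + 1e-12]
            rest_iv = max(preceding, key=lambda r: r[1]) if preceding else seg.rest_interval
        out.append(
            ReachMetrics(
                target=label,
                epd_at_target=interval_mean(iv),
                rest_epd=interval_mean(rest_iv),
            )
        )
    return out


def delta_between_targets(
    metrics: list[ReachMetrics], pairs: list[tuple[str, str]]
) -> dict[tuple[str, str], dict[str, float]]:
    """Differences of per-target mean EPD and AROM between target pairs.

    Returns ``{(ti, tj): {"depd": mean_epd_i - mean_epd_j, "darom": ...}}``.
    """
    groups: dict[str, list[ReachMetrics]] = {}
    for m in metrics:
        groups.setdefault(m.target, []).append(m)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for ti, tj in pairs:
        for name in (ti, tj):
            if name not in groups:
                raise TargetLookupError(f"no reaches recorded for target {name!r}")
        epd_i = float(np.mean([m.epd_at_target for m in groups[ti]]))
        epd_j = float(np.mean([m.epd_at_target for m in groups[tj]]))
        arom_i = float(np.mean([m.arom for m in groups[ti]]))
        arom_j = float(np.mean([m.arom for m in groups[tj]]))
        out[(ti, tj)] = {"depd": epd_i - epd_j, "darom": arom_i - arom_j}
    return out


def sweep_area(traj: WristTrajectory, sweep: Interval | None = None) -> float:
    """Horizontal sweep area in cm².

    Projects the wrist path onto the world X-Y plane and evaluates the
    absolute shoelace sum of the resulting polygon, with implicit closure from
    the last vertex back to the first.  Self-intersecting projections are
    reported as the absolute signed sum (matching common polygon-area
    routines) with a warning.
    """
    t = traj.t
    p = traj.p
    if sweep is not None:
        m = (t >= sweep[0] - 1e-12) & (t <= sweep[1] + 1e-12)
        p = p[m]
    if len(p) < 3:
        raise InsufficientDataError("sweep area needs at least 3 samples")
    x, y = p[:, 0], p[:, 1]
    area = 0.5 * abs(float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))
    try:  # warn on self-intersection; shapely only used for the diagnostic
        from shapely.geometry import LinearRing

        ring = LinearRing(np.column_stack([x, y]))
        if not ring.is_simple:
            warnings.warn(
                "projected sweep path self-intersects; shoelace area reported",
                stacklevel=2,
            )
    except Exception:
        pass
    return area


def snr_diff_coefficients(window: int) -> np.ndarray:
    """One-sided coefficients c_1..c_M of the smooth noise-robust differentiator.

    For an odd window N = 2M+1 the derivative estimate is
    ``f'(x) ~ (1/h) sum_k c_k (f[x+k] - f[x-k])`` with
    ``c_k = [C(2m, m-k+1) - C(2m, m-k-1)] / 2^(2m+1)``, ``m = (N-3)/2``.
    These filters are exact on quadratics and strongly suppress high-frequency
    noise (the frequency response is tangent to zero at the Nyquist rate).
    """
    if window < 5 or window % 2 == 0:
        raise InvalidInputError("window must be an odd integer >= 5")
    M = (window - 1) // 2
    m = (window - 3) // 2

    def c(k: int) -> float:
        def C(nn: int, kk: int) -> int:
            return comb(nn, kk) if 0 <= kk <= nn else 0

        return (C(2 * m, m - k + 1) - C(2 * m, m - k - 1)) / 2.0 ** (2 * m + 1)

    return np.array([c(k) for k in range(1, M + 1)])


def endpoint_speed(traj: WristTrajectory, window: int = 7) -> np.ndarray:
    """Endpoint speed (cm/s): norm of the smooth-noise-robust derivative of p.

    Each axis is differentiated with the fixed-coefficient central filter of
    the given odd window, using reflection padding at the edges, then the
    pointwise 3-D norm is taken.
    """
    t = traj.t
    p = traj.p
    n = len(t)
    if n < window:
        raise InsufficientDataError(f"series of {n} samples shorter than window {window}")
    c = snr_diff_coefficients(window)
    M = len(c)
    dt = float(np.median(np.diff(t)))
    padded = np.pad(p, ((M, M), (0, 0)), mode="reflect")
    v = np.zeros_like(p)
    for k, ck in enumerate(c, start=1):
        v += ck * (padded[M + k : M + k + n] - padded[M - k : M - k + n])
    v /= dt
    return np.linalg.norm(v, axis=-1)


def peak_envelope(speed_series: np.ndarray, t: np.ndarray | None = None) -> np.ndarray:
    """Upper envelope of a speed series by cubic spline through its local maxima.

    The spline passes through every strict local maximum plus both endpoints
    and is evaluated at all sample positions, floored at zero.  With fewer
    than two interior maxima the input is returned unchanged (a spline through
    fewer than three points is degenerate, and a single-peaked profile is its
    own envelope).
    """
    s = np.asarray(speed_series, dtype=float)
    n = len(s)
    x = np.arange(n, dtype=float) if t is None else np.asarray(t, dtype=float)
    (maxima,) = argrelmax(s)
    if len(maxima) < 2:
        return s.copy()
    knots = np.concatenate([[0], maxima, [n - 1]])
    knots = np.unique(knots)
    spline = CubicSpline(x[knots], s[knots])
    return np.maximum(spline(x), 0.0)


def smoothness(
    envelope: np.ndarray,
    t: np.ndarray | None = None,
    sweep: Interval | None = None,
) -> float:
    """Normalized mean endpoint speed: max(envelope) / mean(envelope) over the
    movement interval.  1.0 means perfectly constant speed; a single
    minimum-jerk stroke gives 15/8 = 1.875."""
    e = np.asarray(envelope, dtype=float)
    if sweep is not None:
        if t is None:
            raise InvalidInputError("sweep interval requires sample times")
        t = np.asarray(t, dtype=float)
        e = e[(t >= sweep[0] - 1e-12) & (t <= sweep[1] + 1e-12)]
    if len(e) == 0:
        raise InsufficientDataError("empty interval for smoothness")
    mean = float(e.mean())
    if mean <= 0:
        raise UndefinedMetricError("mean endpoint speed is zero over the interval")
    # max >= mean holds mathematically; guard against rounding in the mean
    return max(1.0, float(e.max()) / mean)
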