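"""Smoothing, differentiation and geometric transforms of pen trajectories.

The raw tablet samples are noisy and quantized to integer device units,
so kinematic quantities (velocity, acceleration, jerk, curvature) are
read off degree-4 smoothing splines fitted independently to x(t) and
y(t).  A quartic spline is the lowest degree whose third derivative is
still continuous, which is what the jerk channels need.

The smoothing strength is set from the data: the residual budget handed
to the spline fitter is ``residual_scale * n * sigma2`` where ``sigma2``
is a robust estimate of the high-frequency noise variance obtained from
third differences of the signal.  Third differences annihilate local
quadratic trend, so on a smooth noiseless signal the estimate collapses
to (nearly) zero and the spline interpolates, while on white noise of
variance s2 it returns s2 and the spline smooths at the noise floor.

Polar channels (radius and unwrapped angle about the spiral centre) and
the three-way pressure segmentation (rising edge / main signal / falling
edge) also live here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.interpolate import UnivariateSpline

from .io_tablet import DrawingRecord

logger = logging.getLogger(__name__)

#: median of (third difference)^2 for iid N(0, 1) noise is 20 * 0.4549...
#: (third differences have variance 20 and the median of a chi^2_1 is 0.4549)
_THIRD_DIFF_MEDIAN_FACTOR = 20.0 * 0.45493642311957185


@dataclass(frozen=True)
class SmoothingConfig:
    """Spline smoothing parameters.

    residual_scale multiplies the automatic residual budget; 0 forces
    interpolation, larger values smooth harder.
    """

    residual_scale: float = 1.0
    degree: int = 4


@dataclass(frozen=True)
class CenterConfig:
    """How to resolve the spiral centre for the polar transform.

    ``auto`` takes the drawing's interior terminal point: of the two ends
    of the stroke, the one closer to the centroid of all points (spirals
    in this test are drawn between the centre and the rim, so one
    terminus sits at the centre).  ``explicit`` uses (x, y).
    """

    mode: Literal["auto", "explicit"] = "auto"
    x: float = 0.0
    y: float = 0.0


@dataclass(frozen=True)
class PressureConfig:
    plateau_frac: float = 0.9


@dataclass
class SmoothedTrajectory:
    """Spline-smoothed drawing signals on the record's time grid.

    All channels are arrays of one common length.  Cartesian kinematics
    are filled by :func:`smooth_and_differentiate`; ``curvature`` by
    :func:`compute_curvature`; the polar channels by
    :func:`polar_transform` (None until then).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    jx: np.ndarray
    jy: np.ndarray
    speed: np.ndarray
    accel_mag: np.ndarray
    jerk_mag: np.ndarray
    pressure: np.ndarray
    curvature: np.ndarray | None = None
    r: np.ndarray | None = None
    theta: np.ndarray | None = None
    drdt: np.ndarray | None = None
    d2rdt2: np.ndarray | None = None
    center: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "vx", "vy", "ax", "ay", "jx", "jy",
                     "speed", "accel_mag", "jerk_mag", "pressure"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name} length mismatch")


@dataclass(frozen=True)
class PressureSegments:
    """Index partition of a record into rising edge / main / falling edge.

    Stored as half-open index intervals that are contiguous, disjoint and
    cover the record: ``[0, rising_end) [rising_end, falling_start)
    [falling_start, n)``.
    """

    rising_end: int
    falling_start: int
    n: int

    def __post_init__(self) -> None:
        if not (0 < self.rising_end <= self.falling_start <= self.n):
            raise ValueError("segment boundaries out of order")

    @property
    def rising(self) -> slice:
        return slice(0, self.rising_end)

    @property
    def main(self) -> slice:
        return slice(self.rising_end, self.falling_start)

    @property
    def falling(self) -> slice:
        return slice(self.falling_start, self.n)


def estimate_noise_variance(y: np.ndarray) -> float:
    """Robust high-frequency noise variance from third differences.

    Third differences annihilate quadratic trend, so the smooth motion
    component contributes only O(y''' dt^3) bias, negligible at tablet
    sampling rates, while iid noise of variance s2 yields s2.
    """
    y = np.asarray(y, dtype=float)
    if len(y) < 4:
        return 0.0
    d3 = np.diff(y, n=3)
    return float(np.median(d3 * d3) / _THIRD_DIFF_MEDIAN_FACTOR)


def _fit_channel_spline(
    t: np.ndarray, y: np.ndarray, config: SmoothingConfig
) -> UnivariateSpline:
    sigma2 = estimate_noise_variance(y)
    # a budget far below the signal scale is numerically indistinguishable
    # from interpolation; clamp to 0 to keep FITPACK's knot search stable
    if sigma2 <= 1e-14 * max(float(np.var(y)), 1.0):
        sigma2 = 0.0
    s = config.residual_scale * len(y) * sigma2
    # FITPACK grumbles when the budget is close to the interpolation
    # limit; the returned spline is still the best found, so demote the
    # convergence chatter to a debug log
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        spl = UnivariateSpline(t, y, k=config.degree, s=s)
    for w in caught:
        logger.debug("spline fit: %s", w.message)
    return spl


def smooth_and_differentiate(
    record: DrawingRecord, smoothing: SmoothingConfig | None = None
) -> SmoothedTrajectory:
    """Fit smoothing splines to x(t), y(t) and evaluate derivatives.

    Derivatives up to order 3 are taken analytically from the spline and
    evaluated on the original (possibly uneven) time grid; speed,
    acceleration magnitude and jerk magnitude are Euclidean norms of the
    vector derivatives.
    """
    smoothing = smoothing or SmoothingConfig()
    t = record.samples["timestamp"].to_numpy(dtype=float)
    if len(t) < 8:
        raise ValueError(f"too few samples ({len(t)}) for spline smoothing")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    channels = {}
    for name in ("x", "y"):
        raw = record.samples[name].to_numpy(dtype=float)
        spl = _fit_channel_spline(t, raw, smoothing)
        channels[name] = [spl.derivative(d)(t) if d else spl(t) for d in range(4)]

    (x, vx, ax, jx), (y, vy, ay, jy) = channels["x"], channels["y"]
    return SmoothedTrajectory(
        t=t,
        x=x, y=y, vx=vx, vy=vy, ax=ax, ay=ay, jx=jx, jy=jy,
        speed=np.hypot(vx, vy),
        accel_mag=np.hypot(ax, ay),
        jerk_mag=np.hypot(jx, jy),
        pressure=record.samples["pressure"].to_numpy(dtype=float),
    )


def compute_curvature(
    traj: SmoothedTrajectory, speed_tol: float = 1e-8
) -> np.ndarray:
    """Planar curvature kappa = |x'y'' - y'x''| / (x'^2 + y'^2)^(3/2).

    Points where the pen speed falls below ``speed_tol`` get NaN (the
    curvature of a stationary pen is undefined); their count is logged.
    The channel is also stored on ``traj``.
    """
    num = np.abs(traj.vx * traj.ay - traj.vy * traj.ax)
    slow = traj.speed < speed_tol
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(slow, np.nan, num / np.maximum(traj.speed, speed_tol) ** 3)
    if slow.any():
        logger.info("curvature: %d stationary points set to NaN", int(slow.sum()))
    traj.curvature = kappa
    return kappa


def resolve_center(
    traj: SmoothedTrajectory, center: CenterConfig | tuple[float, float] | str = "auto"
) -> tuple[float, float]:
    """Resolve the spiral centre point for the polar transform."""
    if isinstance(center, tuple):
        return (float(center[0]), float(center[1]))
    if isinstance(center, CenterConfig):
        if center.mode == "explicit":
            return (center.x, center.y)
    elif center != "auto":
        raise ValueError(f"unknown center mode {center!r}")
    cx, cy = float(np.mean(traj.x)), float(np.mean(traj.y))
    d_first = np.hypot(traj.x[0] - cx, traj.y[0] - cy)
    d_last = np.hypot(traj.x[-1] - cx, traj.y[-1] - cy)
    i = 0 if d_first <= d_last else -1
    return (float(traj.x[i]), float(traj.y[i]))


def polar_transform(
    traj: SmoothedTrajectory,
    center: CenterConfig | tuple[float, float] | str = "auto",
    smoothing: SmoothingConfig | None = None,
) -> SmoothedTrajectory:
    """Fill radius, unwrapped angle and radial derivatives on ``traj``.

    theta is the atan2 angle unwrapped to a continuous signal (jumps
    larger than pi corrected by multiples of 2 pi); monotonicity is *not*
    assumed — tremor can locally reverse the winding.  drdt and d2rdt2
    come from a degree-4 smoothing spline fitted to r(t).
    """
    smoothing = smoothing or SmoothingConfig()
    cx, cy = resolve_center(traj, center)
    dx, dy = traj.x - cx, traj.y - cy
    r = np.hypot(dx, dy)
    if np.all(r < 1e-12):
        raise ValueError("all points coincide with the spiral centre")
    theta = np.unwrap(np.arctan2(dy, dx))
    rspl = _fit_channel_spline(traj.t, r, smoothing)
    traj.r = r
    traj.theta = theta
    traj.drdt = rspl.derivative(1)(traj.t)
    traj.d2rdt2 = rspl.derivative(2)(traj.t)
    traj.center = (cx, cy)
    return traj


def segment_pressure(
    pressure: np.ndarray,
    t: np.ndarray | None = None,
    plateau_frac: float = 0.9,
) -> PressureSegments:
    """Split a pressure signal into rising edge, main signal, falling edge.

    The plateau level is the median of the middle 60% of samples (robust
    to tremor oscillation riding on the plateau); the rising edge runs
    from the start through the first sample at or above
    ``plateau_frac * plateau``, the falling edge from the last such
    sample through the end, and the main signal is the remainder.
    Degenerate overlaps are resolved in favour of the main signal.
    """
    p = np.asarray(pressure, dtype=float)
    n = len(p)
    if n < 3:
        raise ValueError("pressure segmentation needs at least 3 samples")
    if not np.nanmax(p) > 0:
        raise ValueError("pen never touched tablet (all-zero pressure)")
    lo, hi = int(np.floor(0.2 * n)), int(np.ceil(0.8 * n))
    plateau = float(np.median(p[lo:hi])) if hi > lo else float(np.median(p))
    if plateau <= 0:  # pathological signal, fall back to global level
        plateau = float(np.nanmax(p))
    thr = plateau_frac * plateau
    above = np.flatnonzero(p >= thr)
    if above.size == 0:  # threshold never reached: everything is edge
        return PressureSegments(rising_end=n - 1 if n > 1 else 1, falling_start=n - 1, n=n)
    i_r = int(above[0])
    i_f = int(above[-1])
    rising_end = i_r + 1
    falling_start = max(i_f, rising_end)
    return PressureSegments(rising_end=rising_end, falling_start=falling_start, n=n)


@dataclass(frozen=True)
class PreprocessConfig:
    """Bundle of all preprocessing knobs."""

    smoothing: SmoothingConfig = field(default_factory=SmoothingConfig)
    center: CenterConfig = field(default_factory=CenterConfig)
    pressure: PressureConfig = field(default_factory=PressureConfig)
    curvature_speed_tol: float = 1e-8


def preprocess_record(
    record: DrawingRecord, config: PreprocessConfig | None = None
) -> tuple[SmoothedTrajectory, PressureSegments]:
    """Run the full preprocessing chain on one drawing."""
    config = config or PreprocessConfig()
    traj = smooth_and_differentiate(record, config.smoothing)
    compute_curvature(traj, config.curvature_speed_tol)
    polar_transform(traj, config.center, config.smoothing)
    segments = segment_pressure(
        traj.pressure, traj.t, plateau_frac=config.pressure.plateau_frac
    )
    return traj, segments
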