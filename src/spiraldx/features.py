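"""The per-drawing feature battery.

A drawing is reduced to 79 named scalar features exploiting the
mathematical structure of the Archimedean spiral r = a + b*theta:

* 7 signals (velocity, acceleration, jerk, pressure, curvature, drdt,
  d2rdt2) x 7 statistics (mean, standard deviation, max, skewness,
  kurtosis, entropy, rate of inversion) — 49 features;
* 4 linear regressions exploiting the spiral's structural relations
  (radius ~ theta, curvature ~ time, velocity ~ time, velocity ~ radius)
  x {R^2, per-sample sum of squared residuals} — 8 features;
* pressure-signal components (rising edge / main signal / falling edge)
  x {duration, value range} — 6 features;
* global: overall duration, total path length, normal velocity
  variability — 3 features;
* Fourier features of the radius deviation from the fitted spiral form,
  of velocity and of pressure: dominant frequency, dominant-peak power
  fraction, and 4–7 Hz tremor-band power fraction — 9 features;
* pen angles: mean and standard deviation of azimuth and altitude —
  4 features.

A perfect spiral has radius exactly linear in theta, so the
radius ~ theta regression residuals measure deviation from the ideal
form; the rate of inversion in pressure separates smooth tremor
oscillation (one sign change per half-period) from the fine random
fluctuation of a steady hand (a sign change almost every sample).

The registry is the single source of feature names and ordering; the
default registry length is pinned at 79.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy import stats as sp_stats

from .io_tablet import META_COLUMNS, Dataset, DrawingRecord
from .preprocess import (
    PreprocessConfig,
    PressureSegments,
    SmoothedTrajectory,
    preprocess_record,
)

logger = logging.getLogger(__name__)

TREMOR_BAND = (4.0, 7.0)  # Hz, parkinsonian rest-tremor range

_SIGNAL_LABELS = {
    "speed": "Velocity",
    "accel_mag": "Acceleration",
    "jerk_mag": "Jerk",
    "pressure": "Pressure",
    "curvature": "Curvature",
    "drdt": "drdt",
    "d2rdt2": "d2rdt2",
}
_REGRESSION_LABELS = {
    "radius_theta": "Radius vs. Theta Regression",
    "curvature_time": "Curvature vs. Time Regression",
    "speed_time": "Velocity vs. Time Regression",
    "speed_radius": "Velocity vs. Radius Regression",
}
#: signals that exist only through the spline/polar machinery; statistics on
#: them are new to this battery rather than carried over from prior work
_NOVEL_SIGNALS = {"curvature", "drdt", "d2rdt2"}


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    group: str  # summary | inversion | entropy | regression | pressure | fourier | global
    novel: bool = False


class FeatureRegistry:
    """Ordered, named collection of the features the battery computes."""

    def __init__(self, entries: Sequence[FeatureEntry]):
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")
        self.entries: tuple[FeatureEntry, ...] = tuple(entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def manifest(self) -> str:
        """Plain-text manifest: name, group, novel flag."""
        lines = [f"{e.name}\t{e.group}\t{'novel' if e.novel else 'standard'}"
                 for e in self.entries]
        return "\n".join(lines) + "\n"


def default_registry() -> FeatureRegistry:
    entries: list[FeatureEntry] = []
    for sig, label in _SIGNAL_LABELS.items():
        novel = sig in _NOVEL_SIGNALS
        entries.append(FeatureEntry(f"Mean {label}", "summary", novel))
        entries.append(FeatureEntry(f"{label} Standard Deviation", "summary", novel))
        entries.append(FeatureEntry(f"Max {label}", "summary", novel))
        entries.append(FeatureEntry(f"{label} Skewness", "summary", novel))
        entries.append(FeatureEntry(f"{label} Kurtosis", "summary", novel))
        entries.append(FeatureEntry(f"{label} Entropy", "entropy", novel))
        entries.append(FeatureEntry(f"Rate of Inversion in {label}", "inversion", novel))
    for _, label in _REGRESSION_LABELS.items():
        entries.append(FeatureEntry(f"{label} R^2", "regression", True))
        entries.append(FeatureEntry(f"{label} Sum of Residuals", "regression", True))
    for comp in ("Rising Edge", "Main Signal", "Falling Edge"):
        entries.append(FeatureEntry(f"{comp} Duration", "pressure", False))
        entries.append(FeatureEntry(f"{comp} Pressure Range", "pressure", False))
    entries.append(FeatureEntry("Overall Duration", "global", False))
    entries.append(FeatureEntry("Total Path Length", "global", False))
    entries.append(FeatureEntry("Normal Velocity Variability", "global", False))
    for label in ("Radius", "Velocity", "Pressure"):
        entries.append(FeatureEntry(f"{label} Dominant Frequency", "fourier", True))
        entries.append(FeatureEntry(f"{label} Dominant Peak Power Fraction", "fourier", True))
        entries.append(FeatureEntry(f"{label} Tremor Band Power Fraction", "fourier", True))
    for label in ("Azimuth", "Altitude"):
        entries.append(FeatureEntry(f"Mean {label}", "summary", False))
        entries.append(FeatureEntry(f"{label} Standard Deviation", "summary", False))
    return FeatureRegistry(entries)


DEFAULT_REGISTRY = default_registry()
assert len(DEFAULT_REGISTRY) == 79


@dataclass(frozen=True)
class FeatureConfig:
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    entropy_bins: int = 16
    tremor_band: tuple[float, float] = TREMOR_BAND


@dataclass
class FeatureVector:
    """One drawing's feature values, keyed exactly by the registry names."""

    subject_id: str
    label: str
    test_type: str
    values: dict[str, float]
    degenerate: bool = False


@dataclass(frozen=True)
class RegressionFeatures:
    slope: float
    intercept: float
    r_squared: float
    ssr: float


# ---------------------------------------------------------------------------
# elementary statistics


def summary_stats(values: np.ndarray) -> dict[str, float]:
    """Mean, sample std, max, skewness and Fisher kurtosis of a signal.

    Skewness and kurtosis are the standardized third/fourth central
    moments (kurtosis excess, so a normal distribution scores 0); both
    are NaN for constant signals, where they are undefined.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("summary statistics need at least 2 finite values")
    out = {
        "mean": float(np.mean(v)),
        "std": float(np.std(v, ddof=1)),
        "max": float(np.max(v)),
    }
    if v.size >= 3 and np.var(v) > 0:
        out["skewness"] = float(sp_stats.skew(v, bias=True))
        out["kurtosis"] = float(sp_stats.kurtosis(v, fisher=True, bias=True))
    else:
        logger.debug("zero-variance signal: skewness/kurtosis undefined")
        out["skewness"] = math.nan
        out["kurtosis"] = math.nan
    return out


def inversion_rate(values: np.ndarray, t: np.ndarray) -> float:
    """Sign changes of the first-difference sequence, per second.

    Zero differences are skipped: a change is counted whenever the sign
    of the current nonzero difference differs from the previous nonzero
    difference.  A smooth oscillation at f Hz scores about 2f inversions
    per second (one per extremum); fine random fluctuation scores close
    to one inversion per sample interval.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    if len(v) < 3:
        raise ValueError("inversion rate needs at least 3 samples")
    duration = float(t[-1] - t[0])
    if duration <= 0:
        raise ValueError("inversion rate needs positive total duration")
    mask = np.isfinite(v)
    diffs = np.diff(v[mask])
    signs = np.sign(diffs)
    signs = signs[signs != 0]
    count = int(np.count_nonzero(signs[1:] != signs[:-1]))
    return count / duration


def shannon_entropy(values: np.ndarray, n_bins: int = 16) -> float:
    """Plug-in histogram entropy in bits over equal-width bins.

    Bins span [min, max] of the finite values; a constant signal has a
    single occupied bin and entropy 0.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 1:
        raise ValueError("entropy needs at least 1 finite value")
    vmin, vmax = float(np.min(v)), float(np.max(v))
    if vmin == vmax:
        return 0.0
    counts, _ = np.histogram(v, bins=n_bins, range=(vmin, vmax))
    p = counts[counts > 0] / v.size
    return float(-np.sum(p * np.log2(p)))


def linreg_features(x: np.ndarray, y: np.ndarray) -> RegressionFeatures:
    """Ordinary least squares y = a + b x with R^2 and raw SSR.

    A constant response makes R^2 undefined (NaN) with SSR 0; a constant
    predictor is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError("regression needs at least 3 points")
    if np.var(x) == 0:
        raise ValueError("regression predictor has zero variance")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        return RegressionFeatures(slope=0.0, intercept=float(y[0]),
                                  r_squared=math.nan, ssr=0.0)
    res = sp_stats.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ssr = float(np.sum((y - yhat) ** 2))
    return RegressionFeatures(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=1.0 - ssr / sst,
        ssr=ssr,
    )


def normal_velocity_variability(speed: np.ndarray) -> float:
    """Mean absolute deviation of speed from its mean, over mean speed.

    Dimensionless and invariant under rescaling of the speed signal; 0
    for perfectly steady tracing.
    """
    v = np.asarray(speed, dtype=float)
    v = v[np.isfinite(v)]
    m = float(np.mean(v)) if v.size else 0.0
    if m <= 0:
        return math.nan
    return float(np.mean(np.abs(v - m)) / m)


def pressure_component_features(
    segments: PressureSegments, pressure: np.ndarray, t: np.ndarray
) -> dict[str, float]:
    """Duration (s) and value range of each pressure component."""
    p = np.asarray(pressure, dtype=float)
    t = np.asarray(t, dtype=float)
    out: dict[str, float] = {}
    for name, sl in (("Rising Edge", segments.rising),
                     ("Main Signal", segments.main),
                     ("Falling Edge", segments.falling)):
        ps, ts = p[sl], t[sl]
        if ps.size == 0:
            out[f"{name} Duration"] = 0.0
            out[f"{name} Pressure Range"] = 0.0
        else:
            out[f"{name} Duration"] = float(ts[-1] - ts[0])
            out[f"{name} Pressure Range"] = float(np.max(ps) - np.min(ps))
    return out


def fourier_features(
    values: np.ndarray,
    t: np.ndarray,
    band: tuple[float, float] = TREMOR_BAND,
) -> dict[str, float]:
    """Spectral summary: dominant frequency and power fractions.

    The signal is linearly detrended, resampled onto a uniform grid at
    the median sampling rate, and its magnitude-squared DFT spectrum
    taken.  The dominant frequency is the argmax over (0, Nyquist]; the
    peak and tremor-band fractions are relative to total non-DC power.
    Records shorter than 32 samples or 1 s yield NaNs, as does a signal
    with no non-DC power (a constant).
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    nan_out = {"dominant_freq": math.nan, "peak_fraction": math.nan,
               "band_fraction": math.nan}
    mask = np.isfinite(v)
    v, t = v[mask], t[mask]
    if v.size < 32 or (t[-1] - t[0]) < 1.0:
        return nan_out
    if np.ptp(v) == 0:  # constant: no non-DC power by construction
        return nan_out
    fs = 1.0 / float(np.median(np.diff(t)))
    tu = np.arange(t[0], t[-1], 1.0 / fs)
    vu = np.interp(tu, t, v)
    vu = sp_signal.detrend(vu, type="linear")
    spec = np.abs(np.fft.rfft(vu)) ** 2
    freqs = np.fft.rfftfreq(len(vu), d=1.0 / fs)
    power = spec[1:]  # drop DC
    freqs = freqs[1:]
    total = float(np.sum(power))
    if total <= 0 or not np.isfinite(total):
        return nan_out
    k = int(np.argmax(power))
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return {
        "dominant_freq": float(freqs[k]),
        "peak_fraction": float(power[k] / total),
        "band_fraction": float(np.sum(power[in_band]) / total),
    }


# ---------------------------------------------------------------------------
# battery assembly


#: fraction of the maximum radius below which the polar angle is treated
#: as numerically undefined (atan2 near the centre is noise-dominated)
_RADIUS_FLOOR_FRAC = 0.02


def _radius_theta_mask(r: np.ndarray) -> np.ndarray:
    """Samples usable in radius-angle analyses: away from the centre."""
    r = np.asarray(r, dtype=float)
    floor = _RADIUS_FLOOR_FRAC * np.nanmax(r)
    return np.isfinite(r) & (r >= floor)


def radius_theta_residual(
    traj: SmoothedTrajectory,
) -> tuple[np.ndarray, np.ndarray]:
    """Radius deviation from the fitted linear radius-angle relation.

    Returns (residual, t) over the samples passing the radius floor; this
    is the tremor-bearing signal for the radius spectral features.  Falls
    back to the raw radius when the fit is degenerate.
    """
    mask = _radius_theta_mask(traj.r)
    try:
        reg = linreg_features(traj.theta[mask], traj.r[mask])
        resid = traj.r[mask] - (reg.intercept + reg.slope * traj.theta[mask])
        return resid, traj.t[mask]
    except ValueError:
        return traj.r, traj.t


def spiral_regressions(traj: SmoothedTrajectory) -> dict[str, float]:
    """The four structural regressions, as registry-named features.

    SSR is normalized per sample (divided by n) so drawings of different
    lengths are comparable; failures propagate as NaN.  The radius ~ theta
    pair excludes samples within 2% of the maximum radius of the centre,
    where the polar angle is undefined to within noise.
    """
    mask = _radius_theta_mask(traj.r)
    pairs = {
        "radius_theta": (traj.theta[mask], traj.r[mask]),
        "curvature_time": (traj.t, traj.curvature),
        "speed_time": (traj.t, traj.speed),
        "speed_radius": (traj.r, traj.speed),
    }
    out: dict[str, float] = {}
    for key, (x, y) in pairs.items():
        label = _REGRESSION_LABELS[key]
        try:
            reg = linreg_features(x, y)
            n = int(np.sum(np.isfinite(np.asarray(x, float))
                           & np.isfinite(np.asarray(y, float))))
            out[f"{label} R^2"] = reg.r_squared
            out[f"{label} Sum of Residuals"] = reg.ssr / n
        except ValueError:
            out[f"{label} R^2"] = math.nan
            out[f"{label} Sum of Residuals"] = math.nan
    return out


def _signal_block(
    label: str, values: np.ndarray, t: np.ndarray, config: FeatureConfig
) -> dict[str, float]:
    out: dict[str, float] = {}
    finite = np.asarray(values, float)
    finite = finite[np.isfinite(finite)]
    if finite.size < 2:
        stats = {k: math.nan for k in ("mean", "std", "max", "skewness", "kurtosis")}
        ent = math.nan
        inv = math.nan
    else:
        stats = summary_stats(values)
        ent = shannon_entropy(values, config.entropy_bins)
        inv = inversion_rate(values, t) if len(values) >= 3 else math.nan
    out[f"Mean {label}"] = stats["mean"]
    out[f"{label} Standard Deviation"] = stats["std"]
    out[f"Max {label}"] = stats["max"]
    out[f"{label} Skewness"] = stats["skewness"]
    out[f"{label} Kurtosis"] = stats["kurtosis"]
    out[f"{label} Entropy"] = ent
    out[f"Rate of Inversion in {label}"] = inv
    return out


def extract_all(
    record: DrawingRecord,
    config: FeatureConfig | None = None,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
) -> FeatureVector:
    """Compute the full feature battery for one drawing.

    Preprocessing failures (too few samples, degenerate geometry) yield
    an all-NaN vector flagged degenerate rather than an exception, so a
    cohort extraction never dies on one bad record.
    """
    config = config or FeatureConfig()
    names = registry.names
    try:
        traj, segments = preprocess_record(record, config.preprocess)
    except ValueError as exc:
        logger.warning("degenerate drawing %s/%s: %s",
                       record.subject_id, record.test_type, exc)
        return FeatureVector(
            subject_id=record.subject_id,
            label=record.label,
            test_type=record.test_type,
            values={name: math.nan for name in names},
            degenerate=True,
        )

    values: dict[str, float] = {}
    signals = {
        "speed": traj.speed,
        "accel_mag": traj.accel_mag,
        "jerk_mag": traj.jerk_mag,
        "pressure": traj.pressure,
        "curvature": traj.curvature,
        "drdt": traj.drdt,
        "d2rdt2": traj.d2rdt2,
    }
    for sig, label in _SIGNAL_LABELS.items():
        values.update(_signal_block(label, signals[sig], traj.t, config))

    values.update(spiral_regressions(traj))
    values.update(pressure_component_features(segments, traj.pressure, traj.t))

    values["Overall Duration"] = float(traj.t[-1] - traj.t[0])
    values["Total Path Length"] = float(
        np.sum(np.hypot(np.diff(traj.x), np.diff(traj.y)))
    )
    values["Normal Velocity Variability"] = normal_velocity_variability(traj.speed)

    # the radius spectral features act on the deviation from the fitted
    # spiral form: the raw radius is dominated by its own growth trend
    r_resid, r_t = radius_theta_residual(traj)
    for label, sig, sig_t in (("Radius", r_resid, r_t),
                              ("Velocity", traj.speed, traj.t),
                              ("Pressure", traj.pressure, traj.t)):
        ff = fourier_features(sig, sig_t, config.tremor_band)
        values[f"{label} Dominant Frequency"] = ff["dominant_freq"]
        values[f"{label} Dominant Peak Power Fraction"] = ff["peak_fraction"]
        values[f"{label} Tremor Band Power Fraction"] = ff["band_fraction"]

    for col, label in (("azimuth", "Azimuth"), ("altitude", "Altitude")):
        sig = record.samples[col].to_numpy(dtype=float)
        finite = sig[np.isfinite(sig)]
        if finite.size >= 2:
            values[f"Mean {label}"] = float(np.mean(finite))
            values[f"{label} Standard Deviation"] = float(np.std(finite, ddof=1))
        else:
            values[f"Mean {label}"] = math.nan
            values[f"{label} Standard Deviation"] = math.nan

    ordered = {name: float(values[name]) for name in names}
    return FeatureVector(
        subject_id=record.subject_id,
        label=record.label,
        test_type=record.test_type,
        values=ordered,
    )


def extract_table(
    records: Iterable[DrawingRecord] | Dataset,
    config: FeatureConfig | None = None,
    registry: FeatureRegistry = DEFAULT_REGISTRY,
    test_type: str | None = None,
) -> pd.DataFrame:
    """Feature table over a collection of drawings.

    Rows are drawings, columns are ``subject_id, label, test_type``
    followed by the registry features in registry order.
    """
    if isinstance(records, Dataset):
        records = records.records
    rows = []
    for rec in records:
        if test_type is not None and rec.test_type != test_type:
            continue
        fv = extract_all(rec, config, registry)
        row = {"subject_id": fv.subject_id, "label": fv.label,
               "test_type": fv.test_type}
        row.update(fv.values)
        rows.append(row)
    if not rows:
        raise ValueError("no records to extract features from")
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + registry.names)
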