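"""Shared fixtures: hand-built records and scaled-down synthetic cohorts.

Distributional tests run on shortened drawings (8 s at 80 Hz instead of
30 s at 133 Hz) so the suite stays fast; the generative mechanisms are
identical and 80 Hz still oversamples the 4-7 Hz tremor band.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import spiraldx as sx

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_record(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    pressure: np.ndarray | None = None,
    azimuth: float | np.ndarray = 1800.0,
    altitude: float | np.ndarray = 600.0,
    label: str = "control",
    subject_id: str = "s",
    test_type: str = "SST",
) -> sx.DrawingRecord:
    """Build a DrawingRecord from explicit channel arrays."""
    n = len(t)
    samples = pd.DataFrame(
        {
            "x": np.asarray(x, float),
            "y": np.asarray(y, float),
            "z": np.zeros(n),
            "pressure": (
                np.asarray(pressure, float) if pressure is not None
                else np.full(n, 500.0)
            ),
            "azimuth": np.broadcast_to(np.asarray(azimuth, float), (n,)).copy(),
            "altitude": np.broadcast_to(np.asarray(altitude, float), (n,)).copy(),
            "timestamp": np.asarray(t, float),
        }
    )
    return sx.DrawingRecord(subject_id, label, test_type, samples)


def spiral_record(
    a: float = 10.0,
    b: float = 3.0,
    n_rev: int = 3,
    n: int = 800,
    duration: float = 20.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> sx.DrawingRecord:
    """A perfect Archimedean spiral r = a + b*theta traced at constant
    angular speed, exact float coordinates."""
    t = np.linspace(0, duration, n)
    theta = 2 * np.pi * n_rev * t / duration
    r = a + b * theta
    return make_record(t, center[0] + r * np.cos(theta), center[1] + r * np.sin(theta))


#: scaled-down simulation presets used throughout the suite
SMALL_PATIENT = dataclasses.replace(sx.PATIENT_DEFAULT, duration=8.0, sampling_rate=80.0)
SMALL_CONTROL = dataclasses.replace(sx.CONTROL_DEFAULT, duration=8.0, sampling_rate=80.0)

#: still smaller drawings for the many-cohort null-calibration runs
TINY_PATIENT = dataclasses.replace(sx.PATIENT_DEFAULT, duration=6.0, sampling_rate=60.0)
TINY_CONTROL = dataclasses.replace(sx.CONTROL_DEFAULT, duration=6.0, sampling_rate=60.0)

HEADLINE_PAIR = (
    "Rate of Inversion in Pressure",
    "Radius vs. Theta Regression Sum of Residuals",
)


@pytest.fixture(scope="session")
def small_cohort_table() -> pd.DataFrame:
    """Feature table of a 15+15 scaled-down default-preset cohort."""
    spec = sx.CohortSpec(
        n_patients=15, n_controls=15, seed=11,
        patient_params=SMALL_PATIENT, control_params=SMALL_CONTROL,
    )
    return sx.extract_table(sx.simulate_cohort(spec))


@pytest.fixture(scope="session")
def null_mean_auc() -> float:
    """Cohort-averaged mean random-forest AUC on identical-parameter cohorts.

    At 30+30 the empirical class separation of any single null cohort
    still fluctuates with sd ~ 0.05-0.1, so the chance-level check
    averages the repeated-evaluation mean AUC over three independent
    null cohorts.
    """
    aucs = []
    for seed in (101, 102, 103):
        spec = sx.CohortSpec(
            n_patients=30, n_controls=30, seed=seed,
            patient_params=TINY_CONTROL, control_params=TINY_CONTROL,
        )
        table = sx.extract_table(sx.simulate_cohort(spec))
        rep = sx.repeated_evaluation(
            table,
            sx.EvaluationProtocol(HEADLINE_PAIR, n_repeats=25, base_seed=17),
        )
        aucs.append(rep.means["auc"])
    return float(np.mean(aucs))


@pytest.fixture(scope="session")
def null_rejection_rate() -> tuple[float, int]:
    """Pooled per-feature Mann-Whitney rejection rate at alpha=.05 on
    identical-parameter cohorts.

    25 independent 10+10 null cohorts x the non-degenerate features of
    the battery give > 500 pooled feature-level tests; constant and
    all-NaN features are excluded (a rank test can never reject on a
    constant).  Returns (rate, number of pooled tests).
    """
    rejections = []
    for seed in range(300, 325):
        spec = sx.CohortSpec(
            n_patients=10, n_controls=10, seed=seed,
            patient_params=TINY_CONTROL, control_params=TINY_CONTROL,
        )
        table = sx.extract_table(sx.simulate_cohort(spec))
        constant = {
            name for name in sx.DEFAULT_REGISTRY.names
            if table[name].nunique(dropna=True) <= 1
        }
        frame = sx.screen(table).frame
        usable = frame["p"].notna() & ~frame["feature"].isin(constant)
        rejections.extend(frame.loc[usable, "p"] <= 0.05)
    return float(np.mean(rejections)), len(rejections)
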