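"""The feature battery: elementary statistics against hand/brute-force
oracles, the spiral regressions, and the tremor mechanisms the battery
is built to detect."""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import spiraldx as sx
from spiraldx.features import (
    fourier_features,
    inversion_rate,
    linreg_features,
    normal_velocity_variability,
    pressure_component_features,
    shannon_entropy,
    summary_stats,
)
from spiraldx.preprocess import segment_pressure

from conftest import SMALL_CONTROL, SMALL_PATIENT, make_record, spiral_record


class TestSummaryStats:
    def test_constant_signal(self):
        s = summary_stats(np.array([1.0, 1.0, 1.0]))
        assert s["mean"] == 1 and s["std"] == 0 and s["max"] == 1
        assert math.isnan(s["skewness"]) and math.isnan(s["kurtosis"])

    def test_hand_arithmetic(self):
        s = summary_stats(np.array([0.0, 0, 0, 12]))
        assert s["mean"] == 3 and s["std"] == 6 and s["max"] == 12

    def test_normal_draws_have_zero_skew_and_excess_kurtosis(self):
        v = np.random.default_rng(0).standard_normal(100_000)
        s = summary_stats(v)
        assert abs(s["skewness"]) < 0.05
        assert abs(s["kurtosis"]) < 0.05


class TestInversionRate:
    def test_monotone_signal_has_rate_zero(self):
        assert inversion_rate(np.array([1.0, 2, 3, 4]), np.arange(4.0)) == 0.0

    def test_alternating_signal(self):
        # differences (+,-,+,-): 3 changes over 4 s
        rate = inversion_rate(np.array([1.0, 2, 1, 2, 1]), np.linspace(0, 4, 5))
        assert rate == pytest.approx(0.75)

    def test_zero_differences_are_skipped(self):
        # differences (+,0,-): one change
        rate = inversion_rate(np.array([1.0, 2, 2, 1]), np.linspace(0, 3, 4))
        assert rate == pytest.approx(1 / 3)

    @given(st.lists(st.integers(min_value=-3, max_value=3), min_size=3, max_size=30))
    def test_matches_brute_force_enumeration(self, values):
        t = np.arange(len(values), dtype=float)
        # oracle: walk the nonzero difference signs
        signs = [np.sign(d) for d in np.diff(values) if d != 0]
        count = sum(1 for a, b in zip(signs, signs[1:]) if a != b)
        expected = count / (len(values) - 1)
        assert inversion_rate(np.array(values, float), t) == pytest.approx(expected)

    def test_smooth_oscillation_vs_fine_noise_mechanism(self):
        # a smooth 5 Hz oscillation sampled at 133 Hz inverts once per
        # extremum (~10/s); fine noise of comparable short-step magnitude
        # flips sign nearly every sample -> far higher rate
        t = np.arange(0, 10, 1 / 133)
        smooth = 100 * np.sin(2 * np.pi * 5 * t)
        assert inversion_rate(smooth, t) == pytest.approx(10.0, abs=0.5)
        step = float(np.median(np.abs(np.diff(smooth))))
        noisy = smooth + np.random.default_rng(1).normal(0, step, len(t))
        assert inversion_rate(noisy, t) > inversion_rate(smooth, t) + 10


class TestEntropy:
    def test_constant_signal_zero_bits(self):
        assert shannon_entropy(np.full(100, 3.0)) == 0.0

    def test_two_level_signal_one_bit(self):
        v = np.array([0.0] * 50 + [10.0] * 50)
        assert shannon_entropy(v, n_bins=4) == pytest.approx(1.0)

    def test_uniform_draws_approach_log2_bins(self):
        v = np.random.default_rng(2).uniform(size=100_000)
        assert shannon_entropy(v, n_bins=16) == pytest.approx(4.0, abs=0.01)


class TestLinreg:
    def test_exact_line(self):
        x = np.linspace(0, 1, 10)
        reg = linreg_features(x, 2 * x + 1)
        assert reg.slope == pytest.approx(2) and reg.intercept == pytest.approx(1)
        assert reg.r_squared == pytest.approx(1) and reg.ssr == pytest.approx(0, abs=1e-12)

    def test_closed_form_hand_example(self):
        reg = linreg_features(np.array([0.0, 1, 2]), np.array([0.0, 1, 1]))
        assert reg.slope == pytest.approx(0.5)
        assert reg.ssr == pytest.approx(1 / 6)
        assert reg.r_squared == pytest.approx(0.75)

    def test_constant_response(self):
        reg = linreg_features(np.array([0.0, 1, 2]), np.array([5.0, 5, 5]))
        assert math.isnan(reg.r_squared) and reg.ssr == 0

    def test_constant_predictor_is_an_error(self):
        with pytest.raises(ValueError, match="zero variance"):
            linreg_features(np.array([1.0, 1, 1]), np.array([0.0, 1, 2]))

    @given(st.integers(min_value=0, max_value=20))
    def test_matches_matrix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        reg = linreg_features(x, y)
        X = np.column_stack([np.ones_like(x), x])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert reg.intercept == pytest.approx(beta[0])
        assert reg.slope == pytest.approx(beta[1])
        assert reg.ssr == pytest.approx(float(res[0]))


class TestNormalVelocityVariability:
    def test_constant_speed_is_zero(self):
        assert normal_velocity_variability(np.full(10, 3.0)) == 0.0

    def test_hand_example(self):
        assert normal_velocity_variability(np.array([1.0, 3.0])) == pytest.approx(0.5)

    def test_scale_invariance(self):
        v = np.random.default_rng(3).uniform(1, 5, 100)
        assert normal_velocity_variability(7.3 * v) == pytest.approx(
            normal_velocity_variability(v)
        )


class TestPressureComponents:
    def test_trapezoid_durations_and_ranges(self):
        p = np.concatenate([
            np.arange(0, 1000, 100.0), np.full(80, 1000.0),
            np.arange(1000, 0, -100.0),
        ])
        t = np.arange(len(p)) * 0.001  # 1 ms sampling
        seg = segment_pressure(p, plateau_frac=0.9)
        feats = pressure_component_features(seg, p, t)
        assert feats["Rising Edge Duration"] == pytest.approx(0.009)
        assert feats["Rising Edge Pressure Range"] == pytest.approx(900)

    def test_constant_pressure_main_range_zero(self):
        p = np.full(50, 400.0)
        seg = segment_pressure(p)
        feats = pressure_component_features(seg, p, np.arange(50.0))
        assert feats["Main Signal Pressure Range"] == 0.0

    def test_ramp_only_record_falling_duration_zero(self):
        p = np.linspace(0, 1000, 60)
        seg = segment_pressure(p)
        feats = pressure_component_features(seg, p, np.arange(60.0))
        assert feats["Falling Edge Duration"] == 0.0


class TestFourier:
    def test_pure_tone_dominant_frequency_and_band(self):
        t = np.arange(0, 10, 1 / 133)
        ff = fourier_features(np.sin(2 * np.pi * 5 * t), t)
        assert ff["dominant_freq"] == pytest.approx(5.0, abs=0.15)
        assert ff["band_fraction"] > 0.95

    def test_white_noise_band_fraction_matches_flat_spectrum(self):
        t = np.arange(0, 30, 1 / 133)
        v = np.random.default_rng(4).standard_normal(len(t))
        ff = fourier_features(v, t)
        expected = (7 - 4) / (133 / 2)
        assert ff["band_fraction"] == pytest.approx(expected, abs=0.02)

    def test_constant_signal_yields_nans(self):
        t = np.arange(0, 2, 1 / 100)
        ff = fourier_features(np.full(len(t), 5.0), t)
        assert all(math.isnan(v) for v in ff.values())

    def test_short_record_yields_nans(self):
        t = np.linspace(0, 0.5, 40)
        ff = fourier_features(np.sin(t), t)
        assert all(math.isnan(v) for v in ff.values())


_ORIGIN = sx.PreprocessConfig(
    center=sx.CenterConfig(mode="explicit", x=0.0, y=0.0)
)


class TestSpiralRegressions:
    def test_ideal_spiral_radius_theta_is_exact(self):
        traj, _ = sx.preprocess_record(spiral_record(a=10, b=3), _ORIGIN)
        feats = sx.features.spiral_regressions(traj)
        assert feats["Radius vs. Theta Regression R^2"] == pytest.approx(1, abs=1e-9)
        assert feats["Radius vs. Theta Regression Sum of Residuals"] < 1e-6
        # constant angular speed on r = a + b*theta means speed grows
        # linearly-ish; the velocity ~ time regression must be near-perfect
        assert feats["Velocity vs. Time Regression R^2"] > 0.99

    def test_radial_tremor_monotonically_degrades_fit(self):
        # fixed phase/noise, growing tremor amplitude: SSR non-decreasing,
        # R^2 non-increasing
        ssrs, r2s = [], []
        for amp in (0.0, 2.0, 5.0):
            rec = spiral_record(a=10, b=3)
            t = rec.samples["timestamp"].to_numpy()
            x = rec.samples["x"].to_numpy()
            y = rec.samples["y"].to_numpy()
            r = np.hypot(x, y)
            with np.errstate(invalid="ignore"):
                scale = (r + amp * np.sin(2 * np.pi * 5 * t)) / np.where(r > 0, r, 1)
            rec.samples["x"] = x * scale
            rec.samples["y"] = y * scale
            traj, _ = sx.preprocess_record(rec, _ORIGIN)
            feats = sx.features.spiral_regressions(traj)
            ssrs.append(feats["Radius vs. Theta Regression Sum of Residuals"])
            r2s.append(feats["Radius vs. Theta Regression R^2"])
        assert ssrs == sorted(ssrs)
        assert r2s == sorted(r2s, reverse=True)
        assert ssrs[2] > ssrs[0]


class TestExtractAll:
    def test_returns_exactly_the_registry_in_order(self):
        rec = sx.simulate_drawing(SMALL_PATIENT, "patient", np.random.default_rng(0))
        fv = sx.extract_all(rec)
        assert list(fv.values) == sx.DEFAULT_REGISTRY.names
        assert len(fv.values) == 79
        assert all(np.isfinite(v) for v in fv.values.values())

    def test_degenerate_record_yields_all_nan_vector(self):
        t = np.linspace(0, 1, 5)
        fv = sx.extract_all(make_record(t, t, t))
        assert fv.degenerate
        assert all(math.isnan(v) for v in fv.values.values())
        assert list(fv.values) == sx.DEFAULT_REGISTRY.names

    def test_deterministic_on_identical_records(self):
        rec1 = sx.simulate_drawing(SMALL_CONTROL, "control", np.random.default_rng(9))
        rec2 = sx.simulate_drawing(SMALL_CONTROL, "control", np.random.default_rng(9))
        v1 = sx.extract_all(rec1).values
        v2 = sx.extract_all(rec2).values
        assert v1 == v2

    def test_translation_invariance_of_non_positional_features(self):
        # rigid translation of coordinates (centre handled by auto mode)
        rec = sx.simulate_drawing(SMALL_PATIENT, "patient", np.random.default_rng(5))
        shifted = sx.DrawingRecord(
            rec.subject_id, rec.label, rec.test_type, rec.samples.copy()
        )
        shifted.samples["x"] += 500
        shifted.samples["y"] -= 250
        v1 = sx.extract_all(rec).values
        v2 = sx.extract_all(shifted).values
        for name in sx.DEFAULT_REGISTRY.names:
            assert v1[name] == pytest.approx(v2[name], rel=1e-6, abs=1e-9), name


class TestRegistry:
    def test_default_length_is_79(self):
        assert len(sx.DEFAULT_REGISTRY) == 79

    def test_clinically_reported_features_present_by_name(self):
        named = set(sx.DEFAULT_REGISTRY.names)
        for required in [
            "Radius vs. Theta Regression Sum of Residuals",
            "Radius vs. Theta Regression R^2",
            "Rate of Inversion in Pressure",
            "d2rdt2 Standard Deviation",
            "drdt Standard Deviation",
            "Jerk Standard Deviation",
            "Max Jerk",
            "Curvature vs. Time Regression Sum of Residuals",
            "Acceleration Standard Deviation",
            "Velocity vs. Radius Regression Sum of Residuals",
            "Mean Jerk",
            "Max Acceleration",
            "Curvature vs. Time Regression R^2",
            "Velocity vs. Time Regression Sum of Residuals",
            "Velocity Standard Deviation",
        ]:
            assert required in named, required

    def test_manifest_lists_every_feature(self):
        manifest = sx.DEFAULT_REGISTRY.manifest()
        assert len(manifest.strip().splitlines()) == 79
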