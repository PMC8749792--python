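"""Log-calibration curves: conversion, inversion, fitting, registry lookup."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import soundcal as sc
from soundcal.calibration import FITTED_RANGE_DB, is_extrapolated

slopes = st.floats(min_value=5.0, max_value=40.0)
intercepts = st.floats(min_value=-20.0, max_value=20.0)

# printed (model, slope, intercept, R^2) of the five lab-calibrated devices
PROFILES = [
    ("Galaxy S7", 20.5379, 1.3481, 0.9995),
    ("Galaxy A3", 20.7228, 1.2215, 0.9997),
    ("Moto G", 21.216, 14.258, 0.9994),
    ("Moto G 5S Plus", 21.341, 10.166, 0.9998),
    ("Pixel 2", 23.8364, -2.7633, 0.9925),
]


class TestAmplitudeConversion:
    def test_unit_amplitude_returns_intercept_for_all_packaged_profiles(self, registry):
        for model, slope, intercept, r2 in PROFILES:
            cal = registry.calibration_for_model(model)
            assert cal is not None, model
            assert cal.slope_a == slope and cal.r_squared == r2
            assert float(sc.amplitude_to_db(1, cal)) == intercept

    def test_one_decade_adds_the_slope(self, registry, s7):
        assert float(sc.amplitude_to_db(10, s7)) == pytest.approx(21.886, abs=1e-9)
        moto = registry.calibration_for_model("Moto G")
        assert float(sc.amplitude_to_db(10, moto)) == pytest.approx(35.474, abs=1e-9)

    def test_nonpositive_amplitude_rejected(self, s7):
        for bad in (0, -5):
            with pytest.raises(sc.InvalidAmplitudeError):
                sc.amplitude_to_db(bad, s7)

    def test_inversion_examples(self, s7):
        assert sc.db_to_amplitude(1.3481, s7) == pytest.approx(1.0, abs=1e-12)
        assert sc.db_to_amplitude(50.0, s7) == pytest.approx(
            233.8211910218249, abs=1e-9
        )

    def test_round_trip_over_fitted_range(self, s7):
        for level in np.linspace(*FITTED_RANGE_DB, 13):
            x = sc.db_to_amplitude(level, s7)
            assert float(sc.amplitude_to_db(x, s7)) == pytest.approx(level, abs=1e-9)

    @given(a=slopes, b=intercepts, x1=st.floats(1, 3e4), x2=st.floats(1, 3e4))
    @settings(derandomize=True)
    def test_strictly_increasing_in_amplitude(self, a, b, x1, x2):
        cal = sc.DeviceCalibration("synthetic", a, b)
        if x1 != x2:
            lo, hi = sorted((x1, x2))
            assert float(sc.amplitude_to_db(lo, cal)) < float(
                sc.amplitude_to_db(hi, cal)
            )

    def test_extrapolation_tagging(self):
        assert is_extrapolated(49.9) and is_extrapolated(80.1)
        assert not is_extrapolated(50.0) and not is_extrapolated(80.0)


class TestFit:
    @staticmethod
    def _session_from(a, b, levels=tuple(range(50, 85, 5))):
        pts = tuple((float(lv), 10 ** ((lv - b) / a)) for lv in levels)
        return sc.CalibrationSession(points=pts)

    def test_noiseless_points_recover_parameters_exactly(self, s7):
        fit = sc.fit_log_calibration(self._session_from(s7.slope_a, s7.intercept_b))
        assert fit.slope_a == pytest.approx(s7.slope_a, abs=1e-6)
        assert fit.intercept_b == pytest.approx(s7.intercept_b, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    @given(a=slopes, b=intercepts)
    @settings(derandomize=True)
    def test_noiseless_recovery_property(self, a, b):
        fit = sc.fit_log_calibration(self._session_from(a, b))
        assert fit.slope_a == pytest.approx(a, rel=1e-9)
        assert fit.intercept_b == pytest.approx(b, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_two_points_define_an_exact_line(self):
        fit = sc.fit_log_calibration(
            sc.CalibrationSession(points=((50.0, 100.0), (70.0, 1000.0)))
        )
        assert fit.slope_a == pytest.approx(20.0, abs=1e-9)
        assert fit.intercept_b == pytest.approx(10.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_designs_rejected(self):
        with pytest.raises(sc.DegenerateDesignError):
            sc.fit_log_calibration(sc.CalibrationSession(points=((50.0, 100.0),)))
        with pytest.raises(sc.DegenerateDesignError):
            sc.fit_log_calibration(
                sc.CalibrationSession(points=((50.0, 100.0), (55.0, 100.0)))
            )

    def test_noisy_fit_matches_independent_closed_form(self, s7, rng):
        # same seeded data, fitted twice: by the package and by the textbook
        # least-squares formulas written out by hand
        levels = np.arange(50.0, 85.0, 5.0)
        x = np.array([sc.db_to_amplitude(lv, s7) for lv in levels])
        y = levels + rng.normal(0.0, 0.5, size=levels.size)
        fit = sc.fit_log_calibration(sc.CalibrationSession(points=tuple(zip(y, x))))
        lx = np.log10(x)
        slope_ref = np.sum((lx - lx.mean()) * (y - y.mean())) / np.sum(
            (lx - lx.mean()) ** 2
        )
        intercept_ref = y.mean() - slope_ref * lx.mean()
        assert fit.slope_a == pytest.approx(slope_ref, abs=1e-9)
        assert fit.intercept_b == pytest.approx(intercept_ref, abs=1e-9)
        assert fit.slope_a == pytest.approx(s7.slope_a, abs=1.5)
        assert fit.intercept_b == pytest.approx(s7.intercept_b, abs=3.0)
        assert fit.r_squared < 1.0

    @given(a=slopes, b=intercepts, shift=st.floats(-30, 30))
    @settings(derandomize=True, max_examples=50)
    def test_level_shift_moves_only_the_intercept(self, a, b, shift):
        base = self._session_from(a, b)
        shifted = sc.CalibrationSession(
            points=tuple((lv + shift, x) for lv, x in base.points)
        )
        f0, f1 = sc.fit_log_calibration(base), sc.fit_log_calibration(shifted)
        assert f1.slope_a == pytest.approx(f0.slope_a, abs=1e-8)
        assert f1.intercept_b - f0.intercept_b == pytest.approx(shift, abs=1e-7)


class TestOffsetCalibration:
    def test_exact_inversion_of_a_known_profile(self, s7):
        x = sc.db_to_amplitude(50.0, s7)
        cal = sc.offset_calibration((50.0, x), reference_slope=s7.slope_a)
        assert cal.intercept_b == pytest.approx(1.3481, abs=1e-9)
        assert cal.r_squared is None

    def test_plain_arithmetic_case(self):
        cal = sc.offset_calibration((65.0, 1000.0), reference_slope=21.0)
        assert cal.intercept_b == pytest.approx(2.0, abs=1e-12)

    @given(a=slopes, b=intercepts, level=st.floats(40, 90))
    @settings(derandomize=True)
    def test_single_point_recovery(self, a, b, level):
        truth = sc.DeviceCalibration("synthetic", a, b)
        x = sc.db_to_amplitude(level, truth)
        cal = sc.offset_calibration((level, x), reference_slope=a)
        assert cal.intercept_b == pytest.approx(b, abs=1e-7)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(sc.InvalidAmplitudeError):
            sc.offset_calibration((60.0, 0.0), reference_slope=20.0)


class TestRegistry:
    def test_exact_id_match(self, registry):
        model, cal = sc.resolve_device("SM-G930F", registry)
        assert model == "Galaxy S7" and cal.slope_a == 20.5379

    def test_alias_group_match(self, registry):
        # the Moto G family ships under several device IDs
        for device_id in ("XT1028", "Moto G", "XT1032"):
            model, cal = sc.resolve_device(device_id, registry)
            assert model == "Moto G" and cal is not None

    def test_unknown_id_is_a_normal_outcome(self, registry):
        assert sc.resolve_device("NONEXISTENT-ID", registry) == ("unknown", None)

    def test_matching_is_case_sensitive(self, registry):
        assert sc.resolve_device("sm-g930f", registry)[0] == "unknown"

    def test_mapped_but_uncalibrated_devices(self, registry):
        model, cal = sc.resolve_device("SM-G900F", registry)
        assert model == "Galaxy S5" and cal is None

    def test_json_round_trip(self, registry, tmp_path):
        path = tmp_path / "registry.json"
        registry.to_json(path)
        again = sc.DeviceRegistry.from_json(path)
        assert again == registry

    def test_duplicate_ids_rejected(self):
        rec = sc.RegistryRecord(device_id="X", model_name="X phone")
        with pytest.raises(ValueError):
            sc.DeviceRegistry(records=(rec, rec))
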