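import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ramanquant as rq
from ramanquant.errors import ArgumentError
from ramanquant.synthetic import (
    CAL_INTERCEPT,
    CAL_SLOPE,
    GAUSS_AREA_FACTOR,
    Band,
    KineticProfile,
    SceneTruth,
    band_area,
    default_axis,
    logistic_concentration,
)


class TestSimulateSpectrum:
    def test_single_band_peaks_at_center(self):
        s = rq.simulate_spectrum(SceneTruth(bands=[Band("x", 980.0, 8.0, 1000.0)]))
        i = np.argmax(s.intensity)
        assert s.wavenumber[i] == 980.0
        assert s.intensity[i] == pytest.approx(1000.0)

    def test_constant_baseline_only(self):
        s = rq.simulate_spectrum(SceneTruth(baseline_coeffs=(5.0,)))
        np.testing.assert_allclose(s.intensity, 5.0)

    def test_bit_identical_under_fixed_seed(self):
        truth = SceneTruth(
            bands=rq.default_interface_bands(50.0, 1.0, 1.0), noise_sd=2.0, seed=42
        )
        a = rq.simulate_spectrum(truth)
        b = rq.simulate_spectrum(truth)
        assert np.array_equal(a.intensity, b.intensity)

    def test_spike_outside_axis_rejected(self):
        truth = SceneTruth(spike_spec=[(10**6, 100.0)])
        with pytest.raises(ArgumentError, match="spike"):
            rq.simulate_spectrum(truth)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        center=st.floats(400, 2300),
        fwhm=st.floats(4, 40),
        height=st.floats(1, 1e4),
    )
    def test_area_bookkeeping(self, center, fwhm, height):
        """Trapezoidal area over +-5 FWHM matches the analytic Gaussian area."""
        s = rq.simulate_spectrum(SceneTruth(bands=[Band("x", center, fwhm, height)]))
        window = (max(s.wavenumber[0], center - 5 * fwhm),
                  min(s.wavenumber[-1], center + 5 * fwhm))
        numeric = rq.peak_area_numeric(s, window, local_baseline=False)
        analytic = height * fwhm * GAUSS_AREA_FACTOR
        assert numeric == pytest.approx(analytic, rel=1e-6)


class TestDefaultInterfaceBands:
    def test_zero_everything_leaves_only_n2(self):
        bands = rq.default_interface_bands(0.0, 0.0, 0.0)
        assert [b.name for b in bands] == ["N2"]

    def test_ratio_at_50_matches_calibration_line(self):
        bands = rq.default_interface_bands(50.0)
        by_name = {b.name: b for b in bands}
        ratio = by_name["sulfate"].area / by_name["N2"].area
        assert ratio == pytest.approx(0.01802 * 50 - 0.04239, abs=1e-12)
        assert ratio == pytest.approx(0.8586, abs=1e-4)

    def test_ratio_increases_with_concentration(self):
        def ratio(c):
            by_name = {b.name: b for b in rq.default_interface_bands(c)}
            return by_name["sulfate"].area / by_name["N2"].area

        assert ratio(25.0) < ratio(50.0) < ratio(75.0)

    def test_negative_levels_rejected(self):
        with pytest.raises(ArgumentError):
            rq.default_interface_bands(50.0, carotenoid_level=-1.0)

    def test_calibration_series_true_ratio_exact(self):
        """Generator bookkeeping: series at C has true ratio on the line exactly."""
        for conc in (25.0, 60.0, 75.0):
            series = rq.simulate_calibration_series([conc], 1, 0.0, seed=1)
            assert series[0][1].meta["true_ratio"] == pytest.approx(
                CAL_SLOPE * conc + CAL_INTERCEPT, abs=1e-15
            )


class TestCalibrationSeries:
    def test_count(self):
        series = rq.simulate_calibration_series(
            [25, 37.5, 50, 62.5, 75], 3, 5.0, seed=42
        )
        assert len(series) == 15

    def test_zero_noise_replicates_identical(self):
        series = rq.simulate_calibration_series(
            [50.0], 3, 0.0, seed=42, spike_probability=0.0
        )
        a, b, c = (s.intensity for _, s in series)
        assert np.array_equal(a, b) and np.array_equal(b, c)

    def test_deterministic_under_seed(self):
        s1 = rq.simulate_calibration_series([25.0, 50.0], 2, 4.0, seed=42)
        s2 = rq.simulate_calibration_series([25.0, 50.0], 2, 4.0, seed=42)
        for (_, a), (_, b) in zip(s1, s2):
            assert np.array_equal(a.intensity, b.intensity)

    def test_out_of_range_concentration_warns_in_metadata(self):
        series = rq.simulate_calibration_series([10.0], 1, 0.0, seed=1)
        assert "warning" in series[0][1].meta


class TestSimulateMap:
    def test_tiny_radius_on_even_grid_gives_empty_mask(self):
        truth = SceneTruth(bands=rq.default_interface_bands(50.0))
        smap, mask = rq.simulate_map((4, 4), 5.0, truth, truth, seed=1)
        assert not mask.any()

    def test_disc_membership_11x11(self):
        """Radius 40 um at 25 um step covers exactly the 3x3 centre block."""
        truth = SceneTruth(bands=rq.default_interface_bands(50.0))
        smap, mask = rq.simulate_map((11, 11), 40.0, truth, truth, seed=1)
        expected = np.zeros((11, 11), dtype=bool)
        expected[4:7, 4:7] = True
        np.testing.assert_array_equal(mask, expected)

    def test_s8_contrast_inside_vs_outside(self):
        inside = SceneTruth(bands=rq.default_interface_bands(50.0, 0.0, 1.0))
        outside = SceneTruth(bands=rq.default_interface_bands(50.0, 0.0, 0.0))
        smap, mask = rq.simulate_map((5, 5), 40.0, inside, outside, seed=1)
        img = rq.band_image(smap, 470.0)
        assert img.values[mask].mean() > img.values[~mask].mean()

    def test_nonpositive_radius_rejected(self):
        truth = SceneTruth(bands=[])
        with pytest.raises(ArgumentError):
            rq.simulate_map((3, 3), 0.0, truth, truth)


class TestKinetics:
    def test_logistic_limits(self):
        p = KineticProfile(c0=30, c_max=70, t_mid=40, rate=0.15)
        assert logistic_concentration(p, -1e6) == pytest.approx(30.0)
        assert logistic_concentration(p, 1e6) == pytest.approx(70.0)

    def test_light_curve_steeper_at_inflection(self):
        light = KineticProfile(light_factor=1.0)
        dark = KineticProfile(light_factor=0.5)
        delta = 0.5
        slope = lambda p: (
            logistic_concentration(p, p.t_mid + delta)
            - logistic_concentration(p, p.t_mid - delta)
        ) / (2 * delta)
        assert slope(light) > slope(dark)

    def test_timecourse_deterministic(self):
        p = KineticProfile()
        a = rq.simulate_timecourse(p, [0, 24, 48], 2, 3.0, seed=11)
        b = rq.simulate_timecourse(p, [0, 24, 48], 2, 3.0, seed=11)
        for (_, ra), (_, rb) in zip(a, b):
            for sa, sb in zip(ra, rb):
                assert np.array_equal(sa.intensity, sb.intensity)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ArgumentError):
            KineticProfile(c0=70, c_max=30)
        with pytest.raises(ArgumentError):
            KineticProfile(light_factor=0.0)

    def test_decreasing_times_rejected(self):
        with pytest.raises(ArgumentError):
            rq.simulate_timecourse(KineticProfile(), [10, 5], 1, 0.0, seed=1)


class TestSilicon:
    def test_band_sits_at_reference_plus_offset(self):
        s = rq.simulate_silicon(axis_offset=3.0)
        assert s.wavenumber[np.argmax(s.intensity)] == 523.0
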