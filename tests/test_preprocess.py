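import numpy as np
import pytest

import ramanquant as rq
from ramanquant.errors import ArgumentError, CalibrationError
from ramanquant.synthetic import Band, SceneTruth, default_axis


def _noisy_interface(seed=9, noise_sd=5.0):
    truth = SceneTruth(
        bands=rq.default_interface_bands(50.0), noise_sd=noise_sd, seed=seed
    )
    return rq.simulate_spectrum(truth)


class TestDespiking:
    def test_no_false_positives_on_smooth_noiseless_spectrum(self):
        s = rq.simulate_spectrum(
            SceneTruth(bands=rq.default_interface_bands(50.0, 1.0, 1.0))
        )
        out, spikes = rq.remove_cosmic_rays(s)
        assert spikes == []
        assert np.array_equal(out.intensity, s.intensity)

    def test_single_spike_removed_and_repaired(self):
        noise_sd = 5.0
        clean = _noisy_interface(noise_sd=noise_sd)
        spiked = clean.copy()
        spiked.intensity[500] += 100 * noise_sd
        out, spikes = rq.remove_cosmic_rays(
            rq.Spectrum(spiked.wavenumber, spiked.intensity)
        )
        assert set(spikes) <= {499, 500, 501}
        assert 500 in spikes
        assert abs(out.intensity[500] - clean.intensity[500]) < 3 * noise_sd

    def test_adjacent_double_spike_both_replaced(self):
        clean = _noisy_interface()
        spiked = clean.copy()
        spiked.intensity[700] += 600.0
        spiked.intensity[701] += 450.0
        out, spikes = rq.remove_cosmic_rays(
            rq.Spectrum(spiked.wavenumber, spiked.intensity)
        )
        assert {700, 701} <= set(spikes)

    def test_spike_on_band_slope_detected(self):
        """A cosmic ray landing on the sulfate band must still be repaired."""
        clean = _noisy_interface(noise_sd=2.5)
        i = int(np.searchsorted(clean.wavenumber, 982.0))
        spiked = clean.copy()
        spiked.intensity[i] += 5000.0
        out, spikes = rq.remove_cosmic_rays(
            rq.Spectrum(spiked.wavenumber, spiked.intensity)
        )
        assert i in spikes
        assert abs(out.intensity[i] - clean.intensity[i]) < clean.intensity[i] * 0.1

    def test_parameter_validation(self):
        s = _noisy_interface()
        with pytest.raises(ArgumentError):
            rq.remove_cosmic_rays(s, window=4)
        with pytest.raises(ArgumentError):
            rq.remove_cosmic_rays(s, z_thresh=0.0)
        short = rq.Spectrum([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        with pytest.raises(ArgumentError, match="shorter"):
            rq.remove_cosmic_rays(short, window=5)


class TestBaseline:
    def test_zero_baseline_recovered_as_zero(self):
        s = rq.simulate_spectrum(SceneTruth(bands=[Band("x", 980.0, 8.0, 1000.0)]))
        res = rq.correct_baseline(s)
        assert np.abs(res.baseline).max() < 1e-3 * 1000.0

    def test_quadratic_baseline_recovered(self):
        coeffs = (100.0, 0.05, 1e-5)
        s = rq.simulate_spectrum(
            SceneTruth(bands=[Band("x", 980.0, 8.0, 1000.0)], baseline_coeffs=coeffs)
        )
        truth = np.polynomial.polynomial.polyval(s.wavenumber, coeffs)
        for method, kw in [
            ("polynomial", {"degree": 2}),
            ("asymmetric-least-squares", {}),
        ]:
            res = rq.correct_baseline(s, method, **kw)
            assert np.abs(res.baseline - truth).max() < 0.01 * 1000.0, method

    @pytest.mark.parametrize("method,kw", [
        ("asymmetric-least-squares", {}),
        ("polynomial", {"degree": 3}),
    ])
    def test_decomposition_exactly_additive(self, method, kw):
        s = rq.simulate_spectrum(
            SceneTruth(
                bands=rq.default_interface_bands(50.0, 1.0, 1.0),
                baseline_coeffs=(30.0, 0.004),
                noise_sd=12.5,
                seed=3,
            )
        )
        res = rq.correct_baseline(s, method, **kw)
        assert np.array_equal(res.corrected.intensity + res.baseline, s.intensity)

    def test_unknown_method_rejected(self):
        s = _noisy_interface()
        with pytest.raises(ArgumentError, match="unknown"):
            rq.correct_baseline(s, "rubber-band")

    def test_parameter_validation(self):
        s = _noisy_interface()
        with pytest.raises(ArgumentError):
            rq.correct_baseline(s, "asymmetric-least-squares", lam=-1.0)
        with pytest.raises(ArgumentError):
            rq.correct_baseline(s, "asymmetric-least-squares", p=1.5)
        with pytest.raises(ArgumentError):
            rq.correct_baseline(s, "polynomial", degree=9)


class TestWavenumberCalibration:
    def test_zero_offset(self):
        si = rq.simulate_silicon(0.0)
        shift, _ = rq.calibrate_wavenumber(si, si)
        assert shift.offset == pytest.approx(0.0, abs=1e-6)

    def test_three_wavenumber_offset_corrected(self):
        si = rq.simulate_silicon(3.0)
        shift, corrected = rq.calibrate_wavenumber(si, si)
        assert shift.offset == pytest.approx(3.0, abs=1e-6)
        peak = rq.fit_peaks(corrected, (470.0, 570.0), 1)[0]
        assert peak.center == pytest.approx(520.0, abs=0.1)

    def test_idempotent(self):
        si = rq.simulate_silicon(3.0)
        _, corrected = rq.calibrate_wavenumber(si, si)
        shift2, _ = rq.calibrate_wavenumber(corrected, corrected)
        assert shift2.offset == pytest.approx(0.0, abs=1e-6)

    def test_no_band_raises_calibration_error(self):
        flat = rq.Spectrum(default_axis(300.0, 700.0),
                           np.zeros(401), {})
        target = rq.simulate_silicon(0.0)
        with pytest.raises(CalibrationError):
            rq.calibrate_wavenumber(target, flat)


class TestAveraging:
    def test_identical_spectra_mean_equals_input_sd_zero(self):
        s = _noisy_interface()
        mean, sd = rq.average_spectra([s, s.copy(), s.copy()])
        np.testing.assert_allclose(mean.intensity, s.intensity, rtol=1e-14, atol=1e-12)
        np.testing.assert_allclose(sd, 0.0, atol=1e-10)
        assert mean.meta["n_averaged"] == 3

    def test_two_point_formula(self):
        a = rq.Spectrum([1.0, 2.0], [0.0, 0.0])
        b = rq.Spectrum([1.0, 2.0], [2.0, 2.0])
        mean, sd = rq.average_spectra([a, b])
        np.testing.assert_allclose(mean.intensity, [1.0, 1.0])
        np.testing.assert_allclose(sd, [np.sqrt(2.0), np.sqrt(2.0)])

    def test_matches_brute_force_recomputation(self):
        reps = [_noisy_interface(seed=42 + i) for i in range(3)]
        mean, sd = rq.average_spectra(reps)
        stack = np.array([r.intensity for r in reps])
        brute_mean = np.array(
            [sum(stack[:, j]) / 3 for j in range(stack.shape[1])]
        )
        np.testing.assert_array_equal(mean.intensity, stack.mean(axis=0))
        np.testing.assert_allclose(mean.intensity, brute_mean, rtol=1e-15)

    def test_commutes_with_replicate_order(self):
        reps = [_noisy_interface(seed=i) for i in range(3)]
        m1, _ = rq.average_spectra(reps)
        m2, _ = rq.average_spectra(reps[::-1])
        np.testing.assert_allclose(m1.intensity, m2.intensity, rtol=1e-12, atol=1e-13)

    def test_mismatched_axes_rejected(self):
        a = rq.Spectrum([1.0, 2.0], [0.0, 0.0])
        b = rq.Spectrum([1.0, 3.0], [0.0, 0.0])
        with pytest.raises(ArgumentError, match="axis"):
            rq.average_spectra([a, b])

    def test_single_spectrum_rejected(self):
        with pytest.raises(ArgumentError):
            rq.average_spectra([_noisy_interface()])
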