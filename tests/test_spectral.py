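import numpy as np
import pytest

from qusrad.phantom import TissueClassParams, generate_reference
from qusrad.spectral import (
    BSCCurve,
    Spectrum,
    estimate_attenuation,
    estimate_bsc,
    fit_asd_aac,
    linear_spectral_fit,
    model_bsc,
    normalize_spectrum,
    power_spectrum,
)

BAND = (3.0, 8.5)


class TestPowerSpectrum:
    def test_sinusoid_peaks_at_its_frequency(self, acq):
        t = np.arange(512) / acq.sampling_frequency
        rf = np.sin(2 * np.pi * 5.0 * t)[:, None]
        spec = power_spectrum(rf, acq)
        assert spec.frequencies[np.argmax(spec.power)] == pytest.approx(5.0, abs=0.1)

    def test_doubling_amplitude_adds_6db(self, acq):
        rng = np.random.default_rng(0)
        rf = rng.normal(size=(512, 8))
        a = power_spectrum(rf, acq)
        b = power_spectrum(2.0 * rf, acq)
        np.testing.assert_allclose(b.power - a.power, 20 * np.log10(2.0), atol=1e-9)

    def test_white_noise_spectrum_is_flat(self, acq):
        """Fitted slope of a white-noise spectrum averages to ~0 over seeds."""
        slopes = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            spec = power_spectrum(rng.normal(size=(512, 16)), acq)
            slopes.append(linear_spectral_fit(spec, BAND).SS)
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.1)

    def test_short_window_rejected(self, acq):
        with pytest.raises(ValueError, match="minimum"):
            power_spectrum(np.zeros((10, 4)), acq)


class TestNormalization:
    def test_self_normalization_is_zero(self, acq):
        rng = np.random.default_rng(1)
        spec = power_spectrum(rng.normal(size=(256, 8)), acq)
        norm = normalize_spectrum(spec, spec)
        assert np.all(norm.power == 0.0)
        fit = linear_spectral_fit(norm, BAND)
        assert (fit.MBF, fit.SS, fit.SI) == (0.0, 0.0, 0.0)

    def test_constant_offset(self):
        f = np.linspace(0, 12, 100)
        a = Spectrum(f, np.full_like(f, -40.0))
        b = Spectrum(f, np.full_like(f, -43.0))
        np.testing.assert_allclose(normalize_spectrum(a, b).power, 3.0)

    def test_grid_mismatch_rejected(self):
        a = Spectrum(np.linspace(0, 10, 50), np.zeros(50))
        b = Spectrum(np.linspace(0, 12, 50), np.zeros(50))
        with pytest.raises(ValueError, match="grids"):
            normalize_spectrum(a, b)


class TestLinearFit:
    def test_exact_line(self):
        """S(f) = -20 + 2f over 3.0-8.5 MHz: SI -20, SS 2, MBF -8.5."""
        f = np.linspace(0, 12, 241)
        fit = linear_spectral_fit(Spectrum(f, -20.0 + 2.0 * f), BAND)
        assert fit.SI == pytest.approx(-20.0, abs=1e-9)
        assert fit.SS == pytest.approx(2.0, abs=1e-9)
        assert fit.MBF == pytest.approx(-8.5, abs=1e-9)

    def test_mbf_identity(self):
        """MBF == SI + SS * midband on every fit, including noisy input."""
        rng = np.random.default_rng(2)
        for _ in range(25):
            f = np.linspace(0, 12, 120)
            p = rng.normal(-30, 5) + rng.normal(0, 2) * f + rng.normal(0, 1, f.size)
            fit = linear_spectral_fit(Spectrum(f, p), BAND)
            assert fit.MBF == pytest.approx(fit.SI + fit.SS * fit.midband, rel=1e-12)

    def test_too_few_points_rejected(self):
        f = np.linspace(0, 12, 10)
        with pytest.raises(ValueError, match="at least 8"):
            linear_spectral_fit(Spectrum(f, np.zeros_like(f)), (5.0, 6.0))


class TestBSC:
    def test_self_reference_returns_calibration(self, acq):
        rng = np.random.default_rng(3)
        spec = power_spectrum(rng.normal(size=(256, 8)), acq)
        ref = TissueClassParams(effective_scatterer_diameter=100.0, acoustic_concentration=50.0)
        bsc = estimate_bsc(spec, spec, ref, acq)
        expected = model_bsc(spec.frequencies, 100.0, 50.0, acq.speed_of_sound)
        np.testing.assert_allclose(bsc.values, expected)

    def test_10db_offset_scales_10x(self, acq):
        rng = np.random.default_rng(4)
        spec = power_spectrum(rng.normal(size=(256, 8)), acq)
        up = Spectrum(spec.frequencies, spec.power + 10.0)
        ref = TissueClassParams(effective_scatterer_diameter=100.0, acoustic_concentration=50.0)
        base = estimate_bsc(spec, spec, ref, acq)
        shifted = estimate_bsc(up, spec, ref, acq)
        np.testing.assert_allclose(shifted.values, 10.0 * base.values, rtol=1e-10)


class TestASDAAC:
    def test_exact_model_inversion(self):
        """Noise-free model BSC inverts to <= 2% ASD error and exact AAC."""
        f = np.linspace(3.0, 8.5, 40)
        for asd, aac in [(150.0, 60.0), (100.0, 45.0), (220.0, 75.0)]:
            est = fit_asd_aac(BSCCurve(f, model_bsc(f, asd, aac)))
            assert est.ASD == pytest.approx(asd, rel=0.02)
            assert est.AAC == pytest.approx(aac, abs=0.2)

    def test_asd_ordering(self):
        f = np.linspace(3.0, 8.5, 40)
        small = fit_asd_aac(BSCCurve(f, model_bsc(f, 100.0, 60.0)))
        large = fit_asd_aac(BSCCurve(f, model_bsc(f, 180.0, 60.0)))
        assert small.ASD < large.ASD

    def test_amplitude_shape_separability(self):
        """Scaling BSC by 100x adds 20 dB of AAC and leaves ASD unchanged."""
        f = np.linspace(3.0, 8.5, 40)
        base = fit_asd_aac(BSCCurve(f, model_bsc(f, 150.0, 60.0)))
        scaled = fit_asd_aac(BSCCurve(f, 100.0 * model_bsc(f, 150.0, 60.0)))
        assert scaled.AAC - base.AAC == pytest.approx(20.0, abs=1e-6)
        assert scaled.ASD == pytest.approx(base.ASD, rel=1e-4)

    def test_nonpositive_bsc_rejected(self):
        f = np.linspace(3.0, 8.5, 20)
        values = model_bsc(f, 150.0, 60.0)
        values[5] = 0.0
        with pytest.raises(ValueError, match="positive"):
            fit_asd_aac(BSCCurve(f, values))


def _depth_spectra(frame, reference, acq, n_windows=4, window_mm=3.0):
    wlen = int(window_mm / acq.axial_spacing)
    specs, depths = [], []
    for z0 in np.linspace(0, acq.n_axial - wlen, n_windows).astype(int):
        s = power_spectrum(frame.rf[z0 : z0 + wlen, :], acq)
        r = power_spectrum(reference.rf[z0 : z0 + wlen, :], acq)
        specs.append(normalize_spectrum(s, r))
        depths.append((z0 + wlen / 2) * acq.axial_spacing / 10.0)
    return specs, np.array(depths)


class TestAttenuation:
    def test_single_depth_rejected(self):
        f = np.linspace(0, 12, 50)
        with pytest.raises(ValueError, match="two or more"):
            estimate_attenuation([Spectrum(f, np.zeros_like(f))], np.array([1.0]))

    def test_lossless_recovers_zero(self, acq):
        ests = []
        for seed in range(4):
            params = TissueClassParams(attenuation_coefficient=0.0)
            frame = generate_reference(acq, params, seed=seed)
            ref = generate_reference(acq, params, seed=seed + 50)
            specs, depths = _depth_spectra(frame, ref, acq)
            ests.append(estimate_attenuation(specs, depths))
        assert np.mean(ests) == pytest.approx(0.0, abs=0.1)

    def test_recovery_and_linearity(self, acq):
        """0.5 dB/cm/MHz recovered within 20%; doubling the truth roughly
        doubles the estimate."""
        est = {}
        for alpha in (0.5, 1.0):
            vals = []
            for seed in range(5):
                lossy = TissueClassParams(attenuation_coefficient=alpha)
                lossless = TissueClassParams(attenuation_coefficient=0.0)
                frame = generate_reference(acq, lossy, seed=seed)
                ref = generate_reference(acq, lossless, seed=seed + 100)
                specs, depths = _depth_spectra(frame, ref, acq)
                vals.append(estimate_attenuation(specs, depths))
            est[alpha] = np.mean(vals)
        assert est[0.5] == pytest.approx(0.5, rel=0.2)
        assert est[1.0] / est[0.5] == pytest.approx(2.0, rel=0.25)
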