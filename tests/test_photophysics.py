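"""TCSPC lifetimes, binding kinetics, and spectral shape metrics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memquench import (
    DecayTrace,
    EmissionSpectrum,
    InvalidArgumentError,
    KineticTrace,
    OutOfRangeError,
    ScenarioConfig,
    amplitude_weighted_tau,
    correct_scattering,
    durbin_watson,
    fit_binding_kinetics,
    fit_decay,
    intensity_weighted_tau,
    make_decay,
    make_kinetic_trace,
    make_spectrum,
    spectral_shape,
)


class TestAverageLifetime:
    def test_single_component(self):
        assert intensity_weighted_tau([1.0], [8.0]) == 8.0

    def test_three_component_hand_arithmetic(self):
        # sum(a t^2) = 16.625, sum(a t) = 3.25
        tau = intensity_weighted_tau([0.2, 0.3, 0.5], [8.0, 3.0, 1.5])
        assert tau == pytest.approx(16.625 / 3.25)

    def test_equal_lifetimes(self):
        assert intensity_weighted_tau([0.3, 0.7], [4.0, 4.0]) == pytest.approx(4.0)

    @given(
        a=st.lists(st.floats(0.05, 1.0), min_size=2, max_size=4),
        t=st.lists(st.floats(0.5, 10.0), min_size=4, max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_intensity_weighted_exceeds_amplitude_weighted(self, a, t):
        t = t[: len(a)]
        assert intensity_weighted_tau(a, t) >= amplitude_weighted_tau(a, t) - 1e-12


class TestDecayFitting:
    def test_three_component_poisson_recovery(self, stni_chol):
        trace = make_decay(stni_chol, seed=11)
        fit = fit_decay(trace, n_components=3)
        for tau_hat, tau in zip(fit.lifetimes, (8.0, 3.0, 1.5)):
            assert abs(tau_hat - tau) / tau < 0.05
        assert fit.amplitudes.sum() == pytest.approx(1.0)
        assert fit.lifetimes.min() <= fit.tau_avg_intensity <= fit.lifetimes.max()

    def test_single_exponential_self_consistency(self):
        cfg = ScenarioConfig(name="single", lifetimes=((1.0,), (5.0,)))
        trace = make_decay(cfg, poisson=False)
        fit = fit_decay(trace, n_components=1)
        assert fit.lifetimes[0] == pytest.approx(5.0, rel=1e-2)

    def test_irf_only_trace_flagged_degenerate(self, stni_chol):
        trace = make_decay(stni_chol, seed=3)
        irf_trace = DecayTrace(trace.channel_time, trace.irf_counts,
                               trace.irf_counts)
        fit = fit_decay(irf_trace, n_components=1)
        assert "degenerate_lifetime_at_channel_width" in fit.flags

    def test_component_collapse_advises_fewer(self):
        cfg = ScenarioConfig(name="single", lifetimes=((1.0,), (5.0,)))
        trace = make_decay(cfg, seed=2)
        fit = fit_decay(trace, n_components=2)
        assert ("component_collapse_consider_fewer_components" in fit.flags
                or min(fit.amplitudes) < 0.02)

    def test_residuals_unstructured_on_well_specified_model(self, stni_chol):
        dws = []
        for seed in range(50):
            trace = make_decay(stni_chol, seed=100 + seed)
            fit = fit_decay(trace, n_components=3)
            dws.append(durbin_watson(fit.gof.residuals))
        dws = np.array(dws)
        assert np.all((dws > 1.5) & (dws < 2.5))

    def test_invalid_component_count(self, stni_chol):
        trace = make_decay(stni_chol, seed=1)
        with pytest.raises(InvalidArgumentError):
            fit_decay(trace, n_components=5)


class TestBindingKinetics:
    def test_noise_free_recovery(self, stni_chol):
        trace = make_kinetic_trace(stni_chol, noise_cv=0.0)
        fit = fit_binding_kinetics(trace)
        assert fit.amplitude_fractions[0] == pytest.approx(0.85, rel=1e-2)
        assert fit.tau_1 == pytest.approx(3.0, rel=1e-2)
        assert fit.tau_2 == pytest.approx(60.0, rel=1e-2)
        assert fit.F_inf == pytest.approx(1.75, rel=1e-2)
        assert fit.F_0_level == pytest.approx(1.0, rel=1e-2)

    def test_single_exponential_flags_vanishing_amplitude(self):
        t = np.linspace(0, 300, 301)
        y = 1.5 - 0.5 * np.exp(-t / 5.0)
        fit = fit_binding_kinetics(KineticTrace(t, y))
        assert ("single_component_second_amplitude_vanishes" in fit.flags
                or fit.amplitude_fractions.min() < 0.02)

    def test_step_function_flags_time_resolution(self):
        t = np.linspace(0, 300, 301)
        y = np.where(t > 0, 1.5, 1.0)
        fit = fit_binding_kinetics(KineticTrace(t, y))
        assert "tau1_below_time_resolution" in fit.flags

    def test_non_rising_trace_warned(self):
        t = np.linspace(0, 300, 60)
        y = np.full(60, 2.0)
        with pytest.warns(UserWarning, match="rise"):
            fit = fit_binding_kinetics(KineticTrace(t, y))
        assert "non_rising_trace" in fit.flags


class TestScatteringCorrection:
    def test_zero_blank_is_identity(self, stni_chol):
        spec = make_spectrum(stni_chol, noise_cv=0.0, blank_amplitude=1e-12)
        out = correct_scattering(spec)
        assert np.allclose(out.intensity, spec.intensity, atol=1e-10)

    def test_blank_equal_to_spectrum_zeroes_it(self):
        w = np.arange(305.0, 450.0)
        y = np.exp(-((w - 340) ** 2) / 800)
        out = correct_scattering(EmissionSpectrum(w, y, blank=y))
        assert np.all(out.intensity == 0.0)

    def test_recovers_band_area_under_scattering_tail(self, stni_chol):
        spec = make_spectrum(stni_chol, noise_cv=0.0)
        corrected = correct_scattering(spec)
        sd = 55.0 / (2 * np.sqrt(2 * np.log(2)))
        band = np.exp(-((spec.wavelength - 335.0) ** 2) / (2 * sd**2))
        assert np.trapezoid(corrected.intensity, spec.wavelength) == pytest.approx(
            np.trapezoid(band, spec.wavelength), rel=1e-2
        )

    def test_never_negative(self):
        w = np.arange(305.0, 320.0)
        y = np.ones(w.size)
        out = correct_scattering(EmissionSpectrum(w, y, blank=2 * y))
        assert np.all(out.intensity >= 0.0)

    def test_missing_blank_rejected(self):
        w = np.arange(305.0, 320.0)
        with pytest.raises(InvalidArgumentError):
            correct_scattering(EmissionSpectrum(w, np.ones(w.size)))


class TestSpectralShape:
    def _gaussian(self, center=335.0, fwhm=55.0, shift=0.0, scale=1.0):
        w = np.arange(305.0, 451.0)
        sd = fwhm / (2 * np.sqrt(2 * np.log(2)))
        return EmissionSpectrum(w, scale * np.exp(
            -((w - center - shift) ** 2) / (2 * sd**2)))

    def test_gaussian_band_metrics(self):
        shape = spectral_shape(self._gaussian())
        assert shape.lambda_max == pytest.approx(335.0, abs=0.2)
        assert shape.fwhm == pytest.approx(55.0, abs=0.2)

    def test_translation_equivariance(self):
        base = spectral_shape(self._gaussian())
        shifted = spectral_shape(self._gaussian(shift=6.0))
        assert shifted.lambda_max == pytest.approx(base.lambda_max + 6.0,
                                                   abs=1e-9)
        assert shifted.fwhm == pytest.approx(base.fwhm, abs=1e-9)

    def test_scale_invariance(self):
        base = spectral_shape(self._gaussian())
        scaled = spectral_shape(self._gaussian(scale=10.0))
        assert scaled.lambda_max == pytest.approx(base.lambda_max, abs=1e-9)
        assert scaled.fwhm == pytest.approx(base.fwhm, abs=1e-9)

    def test_edge_maximum_rejected(self):
        w = np.arange(305.0, 400.0)
        y = np.linspace(0, 1, w.size)  # maximum at the long-wavelength edge
        with pytest.raises(OutOfRangeError):
            spectral_shape(EmissionSpectrum(w, y))

    def test_tied_maximum_flagged_toward_blue(self):
        w = np.arange(305.0, 400.0)
        y = np.exp(-((w - 350) ** 2) / 500.0)
        y[40] = y.max()  # create an equal earlier maximum
        shape = spectral_shape(EmissionSpectrum(w, y))
        assert "tied_maximum" in shape.flags
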