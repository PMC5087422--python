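"""Wavelet-stage tests: scale map, CWT, energy spectra, delay and mode refinement."""

import numpy as np
import pytest

from gaitevents.wavelet import (
    EnergySpectrum,
    MorletParams,
    cwt_morlet,
    energy_spectrum,
    prior_energy_spectrum,
    scale_delay,
    scale_for_frequency,
    split_and_refine,
)

FS = 148.15
SCALES = np.arange(1, 242)


class TestScaleForFrequency:
    @pytest.mark.parametrize(
        "f,expected", [(0.5, 241), (1.6, 75), (0.8, 150)]
    )
    def test_published_scale_constants(self, f, expected):
        assert scale_for_frequency(f, fc=0.8125, fs=FS) == expected

    def test_unrounded_round_trip_is_exact(self):
        for s in (1.0, 75.0, 150.0, 241.0):
            f = 0.8125 * FS / s
            assert scale_for_frequency(f, rounded=False) == pytest.approx(s, rel=1e-12)

    def test_round_half_up(self):
        # fc*fs/f = 2.5 exactly -> 3 under round-half-up (not banker's 2)
        fc, fs = 1.0, 10.0
        assert scale_for_frequency(4.0, fc=fc, fs=fs) == 3

    def test_nonpositive_frequency_rejected(self):
        with pytest.raises(ValueError):
            scale_for_frequency(0.0)


class TestCwtMorlet:
    def test_zero_signal_gives_zero_scalogram(self):
        W = cwt_morlet(np.zeros(300), SCALES, FS)
        assert np.all(W.W == 0)

    def test_linearity(self, rng):
        x = rng.normal(size=300)
        y = rng.normal(size=300)
        a, b = 2.5, -1.3
        scales = np.arange(1, 242, 20)
        Wxy = cwt_morlet(a * x + b * y, scales, FS).W
        Wx = cwt_morlet(x, scales, FS).W
        Wy = cwt_morlet(y, scales, FS).W
        np.testing.assert_allclose(Wxy, a * Wx + b * Wy, atol=1e-9)

    def test_sinusoid_peak_scale_near_frequency_map(self):
        t = np.arange(300) / FS
        x = np.sin(2 * np.pi * 1.6 * t)
        E = energy_spectrum(cwt_morlet(x, SCALES, FS))
        peak = 1 + int(np.argmax(E.E))
        assert abs(peak - scale_for_frequency(1.6)) <= 3

    def test_explicit_summation_oracle(self):
        """Direct dense evaluation of the CWT definition on a small case."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=64)
        params = MorletParams()
        scales = np.array([3, 10, 25])
        W = cwt_morlet(x, scales, FS)
        for i, s in enumerate(scales):
            for n in (0, 20, 63):
                expected = sum(
                    x[m] * np.conj(params.sample(np.array([(m - n) / s])))[0]
                    for m in range(64)
                ) / np.sqrt(s)
                assert W.W[i, n] == pytest.approx(expected, abs=1e-9)

    def test_agrees_with_pywt_complex_morlet(self):
        """Independent oracle: pywt's cmor with matching bandwidth/centre
        frequency finds the same energy-peak scale for a pure tone."""
        pywt = pytest.importorskip("pywt")
        t = np.arange(3000) / FS
        x = np.sin(2 * np.pi * 1.6 * t)
        E_own = energy_spectrum(cwt_morlet(x, SCALES, FS)).E
        coef, _ = pywt.cwt(x, SCALES, "cmor2.0-0.8125", sampling_period=1 / FS)
        E_ref = np.sum(np.abs(coef) ** 2, axis=1)
        assert int(np.argmax(E_own)) == int(np.argmax(E_ref))

    def test_peak_scale_converges_with_signal_length(self):
        peaks = []
        for n in (300, 3000):
            t = np.arange(n) / FS
            E = energy_spectrum(cwt_morlet(np.sin(2 * np.pi * 1.6 * t), SCALES, FS))
            peaks.append(1 + int(np.argmax(E.E)))
        predicted = scale_for_frequency(1.6)
        assert abs(peaks[1] - predicted) <= abs(peaks[0] - predicted) + 1
        assert abs(peaks[1] - predicted) <= 3

    def test_empty_scale_grid_rejected(self):
        with pytest.raises(ValueError):
            cwt_morlet(np.zeros(10), np.array([]), FS)


class TestEnergySpectrum:
    def test_zero_scalogram(self):
        E = energy_spectrum(cwt_morlet(np.zeros(100), np.array([1, 2, 3]), FS))
        assert np.all(E.E == 0)

    def test_quadratic_scaling(self, rng):
        x = rng.normal(size=300)
        scales = np.arange(1, 50)
        E1 = energy_spectrum(cwt_morlet(x, scales, FS)).E
        E3 = energy_spectrum(cwt_morlet(3.0 * x, scales, FS)).E
        np.testing.assert_allclose(E3, 9.0 * E1, rtol=1e-9)

    def test_matches_double_loop_oracle(self, rng):
        x = rng.normal(size=300)
        scales = np.array([5, 40, 100])
        W = cwt_morlet(x, scales, FS)
        E = energy_spectrum(W).E
        for i in range(len(scales)):
            expected = sum(abs(W.W[i, n]) ** 2 for n in range(300))
            assert E[i] == pytest.approx(expected, rel=1e-9)


class TestPriorSpectrum:
    def test_value_at_event_mode(self):
        E = prior_energy_spectrum(241)
        # exp(0) + exp(-((75-150)/25)^2) = 1 + e^-9
        assert E.value_at(75) == pytest.approx(1 + np.exp(-9.0), abs=1e-12)

    def test_value_at_cycle_mode(self):
        E = prior_energy_spectrum(241)
        # exp(-((150-75)/15)^2) + exp(0) = 1 + e^-25
        assert E.value_at(150) == pytest.approx(1 + np.exp(-25.0), abs=1e-12)

    def test_global_maximum_at_event_mode(self):
        E = prior_energy_spectrum(241)
        assert 1 + int(np.argmax(E.E)) == 75

    def test_invalid_mode_order_rejected(self):
        with pytest.raises(ValueError):
            prior_energy_spectrum(100, mu_e=80, mu_c=60)


class TestScaleDelay:
    def _shift(self, E: EnergySpectrum, k: int) -> EnergySpectrum:
        out = np.zeros_like(E.E)
        if k >= 0:
            out[k:] = E.E[: len(E.E) - k]
        else:
            out[:k] = E.E[-k:]
        return EnergySpectrum(E=out)

    def test_identical_spectra_give_zero_delay(self):
        E = prior_energy_spectrum(241)
        assert scale_delay(E, E) == 0

    @pytest.mark.parametrize("k", [20, -10])
    def test_constructed_shift_recovered(self, k):
        E = prior_energy_spectrum(241)
        assert scale_delay(E, self._shift(E, k)) == k

    def test_exhaustive_shift_recovery(self):
        E = prior_energy_spectrum(241)
        for k in range(-40, 41):
            assert scale_delay(E, self._shift(E, k)) == k

    def test_amplitude_invariance(self):
        E = prior_energy_spectrum(241)
        scaled = EnergySpectrum(E=37.0 * self._shift(E, 12).E)
        assert scale_delay(E, scaled) == 12

    def test_all_zero_observed_rejected(self):
        E = prior_energy_spectrum(241)
        with pytest.raises(ValueError, match="all zero"):
            scale_delay(E, EnergySpectrum(E=np.zeros(241)))


class TestSplitAndRefine:
    def test_prior_as_observation_recovers_modes(self):
        E = prior_energy_spectrum(241)
        est = split_and_refine(E, tau=0)
        assert est.mu_e_hat == 75
        assert est.mu_c_hat == 150
        assert 105 <= est.s_lambda <= 120  # inter-mode valley of the mixture

    def test_constructed_bimodal_spectrum(self):
        s = np.arange(1, 242, dtype=float)
        E = EnergySpectrum(
            E=np.exp(-(((s - 60) / 12) ** 2)) + 0.8 * np.exp(-(((s - 170) / 20) ** 2))
        )
        tau = scale_delay(prior_energy_spectrum(241), E)
        est = split_and_refine(E, tau)
        assert est.mu_e_hat == 60
        assert est.mu_c_hat == 170

    def test_unimodal_degenerate_contract(self):
        s = np.arange(1, 242, dtype=float)
        E = EnergySpectrum(E=np.exp(-(((s - 120) / 30) ** 2)))
        est = split_and_refine(E, tau=0)
        # argmin of a monotone restriction sits at an interval endpoint
        assert est.s_lambda in (75, 150)
        assert 1 <= est.mu_e_hat <= est.s_lambda <= est.mu_c_hat <= 241

    def test_ordering_invariant_on_random_spectra(self, rng):
        for _ in range(50):
            E = EnergySpectrum(E=rng.random(241))
            est = split_and_refine(E, tau=int(rng.integers(-60, 60)))
            assert 1 <= est.mu_e_hat <= est.s_lambda <= est.mu_c_hat <= 241

    def test_interval_outside_grid_rejected(self):
        E = prior_energy_spectrum(241)
        with pytest.raises(ValueError):
            split_and_refine(E, tau=500)
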