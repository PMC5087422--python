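"""Observation-window calibration: bands, regions, event classification, thresholds."""

from dataclasses import replace

import numpy as np
import pytest

from gaitevents.calibration import (
    CalibrationError,
    EventBand,
    ObservationWindow,
    ThresholdSet,
    calibrate_window,
    compute_thresholds,
    detect_window_events,
    extract_bands,
    segment_regions,
)
from gaitevents.events import EventKind, GaitEvent
from gaitevents.preprocess import highpass_accel, smoothed_jerk
from gaitevents.synthetic import generate_trial, terrain_presets
from gaitevents.wavelet import MorletParams, ScaleEstimate, cwt_morlet

from conftest import FS


def _window_from_trial(trial, window_len=300):
    jerk = smoothed_jerk(highpass_accel(trial.accel))
    start = trial.truth[0].n
    return ObservationWindow.from_trace(jerk, start, window_len)


class TestExtractBands:
    def test_zero_scalogram_gives_zero_bands(self):
        W = cwt_morlet(np.zeros(300), np.arange(1, 242), FS)
        est = ScaleEstimate(tau=0, s_lambda=110, mu_e_hat=75, mu_c_hat=150)
        bands = extract_bands(W, est)
        assert np.allclose(bands.x_e, 0) and np.allclose(bands.x_c, 0)

    def test_band_oscillates_at_signal_frequency(self):
        t = np.arange(1482) / FS  # 10 s
        x = np.sin(2 * np.pi * 1.6 * t)
        scales = np.arange(1, 242)
        W = cwt_morlet(x, scales, FS)
        from gaitevents.wavelet import energy_spectrum

        peak_scale = 1 + int(np.argmax(energy_spectrum(W).E))
        est = ScaleEstimate(tau=0, s_lambda=200, mu_e_hat=peak_scale, mu_c_hat=241)
        bands = extract_bands(W, est)
        spec = np.abs(np.fft.rfft(bands.x_e))
        freqs = np.fft.rfftfreq(len(bands.x_e), 1 / FS)
        dominant = freqs[np.argmax(spec)]
        assert abs(dominant - 1.6) <= freqs[1]  # within one FFT bin

    def test_lowpass_preserves_slow_component(self):
        t = np.arange(1482) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        W = cwt_morlet(x, np.arange(1, 242), FS)
        est = ScaleEstimate(tau=0, s_lambda=150, mu_e_hat=120, mu_c_hat=180)
        raw = np.real(W.row(120))
        filtered = extract_bands(W, est, cutoff=10.0).x_e
        assert np.max(np.abs(filtered[200:-200])) == pytest.approx(
            np.max(np.abs(raw[200:-200])), rel=0.02
        )

    def test_off_grid_scale_rejected(self):
        W = cwt_morlet(np.random.default_rng(0).normal(size=300), np.arange(1, 242), FS)
        est = ScaleEstimate(tau=0, s_lambda=110, mu_e_hat=75, mu_c_hat=150)
        bad = replace(est, mu_e_hat=75)
        with pytest.raises(ValueError):
            extract_bands(replace(W, scales=np.arange(2, 243)), replace(bad, mu_e_hat=1))


class TestSegmentRegions:
    def test_cosine_minima_define_regions(self):
        T = 100
        n = np.arange(3 * T + 1)
        x = -np.cos(2 * np.pi * n / T)  # minima at 0, T, 2T, 3T; interior: T, 2T
        regions = segment_regions(x)
        assert regions == [(0, T), (T, 2 * T), (2 * T, 3 * T)]

    def test_single_negative_peak_splits_window(self):
        x = np.zeros(300)
        x[149] = -0.5
        x[148] = x[150] = -0.1  # strict local minimum at 149, value < 0
        x -= 0.01
        regions = segment_regions(x)
        assert regions == [(0, 149), (149, 299)]

    def test_strictly_positive_signal_rejected(self):
        with pytest.raises(CalibrationError):
            segment_regions(np.abs(np.sin(np.arange(300) / 10.0)) + 0.1)

    def test_shared_boundaries(self):
        rng = np.random.default_rng(3)
        x = np.sin(2 * np.pi * np.arange(300) / 60.0) + 0.01 * rng.normal(size=300)
        regions = segment_regions(x)
        for (a1, b1), (a2, b2) in zip(regions, regions[1:]):
            assert b1 == a2


class TestDetectWindowEvents:
    def test_noiseless_window_events_match_truth(self, noiseless_level_trial):
        trial = noiseless_level_trial
        win = _window_from_trial(trial)
        cal = calibrate_window(win)
        # an event whose (lagged) jerk peak falls on the window edge is not
        # recoverable; 45 samples covers the smoothing + burst-peak lag
        in_window = [
            e for e in trial.truth if win.start <= e.n < win.start + win.window_len - 45
        ]
        assert len(cal.events) >= len(in_window) >= 3
        # kinds alternate and times sit a fixed smoothing lag after the truth
        kinds = [e.kind for e in cal.events]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        for det, true in zip(cal.events, in_window):
            assert det.kind == true.kind
            lag = det.t - true.t
            assert 0.1 < lag < 0.3  # smoothing + burst-peak offset
            assert abs(lag - 0.205) < 0.04

    def test_constant_jerk_region_tie_breaks_to_smallest_index(self):
        win = ObservationWindow(J=np.ones(300), fs=FS, start=0)
        x_e = -np.cos(2 * np.pi * np.arange(300) / 100.0)
        x_c = np.cos(2 * np.pi * np.arange(300) / 200.0)
        events = detect_window_events(win, EventBand(x_e=x_e, x_c=x_c), r_b=0.8)
        # J constant: every region's argmax is its first sample
        region_starts = {0, 100, 200}
        assert {e.n for e in events} <= region_starts

    def test_single_cycle_window_has_both_kinds(self, noiseless_level_trial):
        trial = noiseless_level_trial
        win = _window_from_trial(trial, window_len=220)  # ~1.3 cycles
        cal = calibrate_window(win)
        kinds = {e.kind for e in cal.events}
        assert kinds == {EventKind.HS, EventKind.TO}


class TestComputeThresholds:
    def _win(self, J=None):
        return ObservationWindow(J=np.asarray(J if J is not None else np.ones(300)), fs=FS, start=0)

    def test_arithmetic_means_of_listed_events(self):
        events = [
            GaitEvent(EventKind.HS, n=74, t=0.5, amplitude=4.0),
            GaitEvent(EventKind.TO, n=178, t=1.2, amplitude=2.0),
            GaitEvent(EventKind.HS, n=252, t=1.7, amplitude=4.4),
        ]
        th = compute_thresholds(events, self._win())
        assert th.TH3 == pytest.approx(4.2)
        assert th.TH4 == pytest.approx(2.0)
        assert th.T_swin == pytest.approx(0.5)
        assert th.T_std == pytest.approx(0.7)

    def test_median_baseline_robust_to_outlier(self):
        th = compute_thresholds(
            [
                GaitEvent(EventKind.HS, 0, 0.1, 5.0),
                GaitEvent(EventKind.TO, 1, 0.9, 3.0),
                GaitEvent(EventKind.HS, 2, 1.4, 5.0),
            ],
            self._win(J=np.array([1.0, 2.0, 3.0, 4.0, 100.0])),
        )
        assert th.TH2 == 3.0

    def test_missing_kind_names_what_is_missing(self):
        events = [GaitEvent(EventKind.HS, 0, 0.5, 4.0), GaitEvent(EventKind.HS, 1, 1.5, 4.0)]
        with pytest.raises(CalibrationError, match="TO"):
            compute_thresholds(events, self._win())

    def test_recovered_swing_time_near_programmed(self):
        """Calibration recovers the generator's programmed swing duration."""
        profile = terrain_presets()["level"]
        programmed_swing = profile.swing_frac / profile.cadence
        errs = []
        for seed in range(20):
            trial = generate_trial(profile, duration=8.0, seed=seed)
            win = _window_from_trial(trial)
            th = calibrate_window(win).thresholds
            errs.append(abs(th.T_swin - programmed_swing) / programmed_swing)
        assert np.median(errs) < 0.10
        assert np.mean(np.array(errs) < 0.10) >= 0.8

    def test_membership_range_validated(self):
        with pytest.raises(ValueError):
            ThresholdSet(TH2=1, TH3=2, TH4=2, T_swin=0.4, T_std=0.6, r1=1.5)


class TestEndToEndInvariances:
    def test_offset_before_jerk_leaves_thresholds_unchanged(self, noiseless_level_trial):
        """A constant acceleration offset vanishes under differentiation."""
        trial = noiseless_level_trial
        th1 = calibrate_window(_window_from_trial(trial)).thresholds

        axes = trial.accel.axes + np.array([0.4, -0.7, 0.2])
        from conftest import make_trace

        shifted = make_trace(axes)
        jerk = smoothed_jerk(highpass_accel(shifted))
        win = ObservationWindow.from_trace(jerk, trial.truth[0].n, 300)
        th2 = calibrate_window(win).thresholds
        assert th2.TH2 == pytest.approx(th1.TH2, rel=1e-6)
        assert th2.TH3 == pytest.approx(th1.TH3, rel=1e-6)
        assert th2.T_swin == pytest.approx(th1.T_swin, abs=1e-9)

    def test_scaling_acceleration_scales_amplitudes_not_durations(self, noiseless_level_trial):
        trial = noiseless_level_trial
        th1 = calibrate_window(_window_from_trial(trial)).thresholds

        from conftest import make_trace

        c = 2.5
        scaled = make_trace(c * trial.accel.axes)
        jerk = smoothed_jerk(highpass_accel(scaled))
        win = ObservationWindow.from_trace(jerk, trial.truth[0].n, 300)
        th2 = calibrate_window(win).thresholds
        assert th2.TH2 == pytest.approx(c * th1.TH2, rel=1e-6)
        assert th2.TH3 == pytest.approx(c * th1.TH3, rel=1e-6)
        assert th2.TH4 == pytest.approx(c * th1.TH4, rel=1e-6)
        assert th2.T_swin == pytest.approx(th1.T_swin, abs=1e-9)
        assert th2.T_std == pytest.approx(th1.T_std, abs=1e-9)

    def test_event_times_strictly_increasing(self, noisy_level_trial):
        cal = calibrate_window(_window_from_trial(noisy_level_trial))
        times = [e.t for e in cal.events]
        assert all(a < b for a, b in zip(times, times[1:]))
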