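import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retinaosc.filtering import PLANAR_PROFILE, apply_filter
from retinaosc.io import Band, TraceView
from retinaosc.oscillations import (
    DeflectionEvent,
    SpectralPeak,
    Taper,
    classify_oscillatory,
    compute_spectrum,
    count_deflections_windowed,
    detect_deflections,
    detect_oscillation_bouts,
    detect_spectral_peaks,
    fundamental_frequency,
    harmonic_groups,
    phase_locking,
)
from retinaosc.spikes import SpikeTrain
from retinaosc.synthetic import _add_at, _gaussian_deflection, make_preset, simulate_recording

FS = 10_000.0


def _lfp(x, t0=0.0):
    return TraceView(np.asarray(x, float), FS, t0, "ch0", Band.LFP)


def _pulse_train(f0, duration_s=60.0, amp=-300.0, width_ms=80.0):
    """Noise-free periodic deflection train (harmonic-rich)."""
    x = np.zeros(int(duration_s * FS))
    w = _gaussian_deflection(width_ms, FS)
    t = 0.5 / f0
    while t < duration_s - 0.2:
        _add_at(x, w, int(round(t * FS)), -amp)
        t += 1.0 / f0
    return x


class TestSpectrum:
    def test_pure_sinusoid_single_peak_at_its_frequency(self, sine_trace):
        spec = compute_spectrum(sine_trace(2.0, duration_s=10.0, band=Band.LFP))
        assert spec.amp.max() == 1.0
        assert spec.freqs_hz[np.argmax(spec.amp)] == pytest.approx(2.0, abs=1e-9)
        assert spec.df_hz == pytest.approx(0.1)

    def test_two_tone_amplitude_ratio_preserved(self):
        t = np.arange(int(40 * FS)) / FS
        x = np.sin(2 * np.pi * 2 * t) + 0.5 * np.sin(2 * np.pi * 4 * t)
        spec = compute_spectrum(_lfp(x))
        a2 = spec.amp[np.argmin(np.abs(spec.freqs_hz - 2.0))]
        a4 = spec.amp[np.argmin(np.abs(spec.freqs_hz - 4.0))]
        assert a2 == pytest.approx(1.0)
        assert a2 / a4 == pytest.approx(2.0, rel=0.01)

    def test_white_noise_spectrum_basically_flat(self):
        """Max/median ratio in 0.5-20 Hz stays below the oscillatory threshold."""
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(int(60 * FS))
            lfp = apply_filter(TraceView(x, FS, 0.0, "c", Band.RAW), PLANAR_PROFILE.lfp)
            spec = compute_spectrum(lfp)
            band = spec.amp[(spec.freqs_hz > 0.5) & (spec.freqs_hz <= 20.0)]
            assert band.max() / np.median(band) < 5.0

    def test_constant_input_flagged_flat(self):
        spec = compute_spectrum(_lfp(np.full(int(20 * FS), 7.0)))
        assert spec.flat
        assert np.all(spec.amp == 0.0)

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrum(_lfp(np.zeros(int(5 * FS))), window_s=10.0)

    def test_band_limited_to_lfp_range(self, sine_trace):
        spec = compute_spectrum(sine_trace(2.0, band=Band.LFP))
        assert spec.freqs_hz[-1] <= 50.0


class TestPeaksAndFundamental:
    def test_pulse_train_shows_harmonic_stack(self):
        spec = compute_spectrum(_lfp(_pulse_train(3.4)))
        peaks = detect_spectral_peaks(spec)
        freqs = [p.f_hz for p in peaks]
        for expected in (3.4, 6.8, 10.2):
            assert any(abs(f - expected) < 0.1 for f in freqs)

    def test_single_sinusoid_single_peak(self, sine_trace):
        spec = compute_spectrum(sine_trace(2.0, duration_s=20.0, band=Band.LFP))
        assert len(detect_spectral_peaks(spec)) == 1

    def test_flat_spectrum_no_peaks(self):
        spec = compute_spectrum(_lfp(np.full(int(20 * FS), 1.0)))
        assert detect_spectral_peaks(spec) == []

    def test_fundamental_wins_over_larger_harmonic(self):
        peaks = [
            SpectralPeak(3.4, 0.8, 0.8),
            SpectralPeak(6.8, 1.0, 1.0),  # largest single amplitude
            SpectralPeak(10.2, 0.3, 0.3),
        ]
        assert fundamental_frequency(peaks) == pytest.approx(3.4, abs=0.05)
        assert peaks[1].is_harmonic_of is peaks[0]

    def test_single_peak_is_its_own_fundamental(self):
        assert fundamental_frequency([SpectralPeak(1.98, 1.0, 1.0)]) == pytest.approx(1.98)

    def test_non_harmonic_peaks_form_separate_fundamentals(self):
        peaks = [SpectralPeak(2.0, 1.0, 1.0), SpectralPeak(5.0, 0.5, 0.5)]
        assert fundamental_frequency(peaks) == pytest.approx(2.0)
        groups = harmonic_groups(peaks)
        assert len(groups) == 2
        assert groups[1][0] == pytest.approx(5.0)

    def test_no_peaks_returns_none(self):
        assert fundamental_frequency([]) is None

    @pytest.mark.parametrize("f0", [1.98, 2.0, 3.4])
    def test_noiseless_frequency_recovery_never_a_harmonic(self, f0):
        spec = compute_spectrum(_lfp(_pulse_train(f0)))
        est = fundamental_frequency(detect_spectral_peaks(spec))
        assert est == pytest.approx(f0, abs=spec.df_hz / 2)


class TestDeflections:
    def test_noise_free_recovery(self):
        times = [3.0, 8.0, 15.0, 22.0, 30.0, 41.0, 55.0]
        x = np.zeros(int(60 * FS))
        w = _gaussian_deflection(80.0, FS)
        for t in times:
            _add_at(x, w, int(round(t * FS)), 300.0)
        x += np.random.default_rng(0).normal(0.0, 2.0, x.size)
        events = detect_deflections(_lfp(x))
        assert len(events) == 7
        assert np.max(np.abs([e.t_trough for e in events] - np.asarray(times))) < 5e-3
        assert all(e.amplitude_uv < 0 for e in events)

    def test_positive_transients_ignored(self):
        x = np.zeros(int(30 * FS))
        w = _gaussian_deflection(80.0, FS)
        for t in (5.0, 15.0, 25.0):
            _add_at(x, w, int(round(t * FS)), -300.0)  # positive-going
        x += np.random.default_rng(1).normal(0.0, 2.0, x.size)
        assert detect_deflections(_lfp(x)) == []

    def test_close_events_merged_keeping_deeper(self):
        x = np.zeros(int(20 * FS))
        w = _gaussian_deflection(30.0, FS)
        _add_at(x, w, int(5.00 * FS), 200.0)
        _add_at(x, w, int(5.06 * FS), 400.0)  # deeper, 60 ms later
        x += np.random.default_rng(2).normal(0.0, 2.0, x.size)
        events = detect_deflections(_lfp(x), min_separation_ms=100.0)
        assert len(events) == 1
        assert events[0].t_trough == pytest.approx(5.06, abs=0.01)

    def test_detector_matches_injected_ground_truth(self):
        """Full chain on a 120-s aged-RCS simulation recovers injected events."""
        preset = make_preset("RCS_M19")
        rec, truth = simulate_recording(preset, 120.0, seed=3)
        lfp = apply_filter(rec.channel(0), PLANAR_PROFILE.lfp, band=Band.LFP)
        events = detect_deflections(lfp)
        n_inj = len(truth.deflection_times)
        assert abs(len(events) - n_inj) / n_inj <= 0.15


class TestWindowedCounts:
    def test_example_counts(self):
        events = [DeflectionEvent(t, -100.0, 50.0) for t in (1.0, 2.0, 7.0)]
        np.testing.assert_array_equal(
            count_deflections_windowed(events, 10.0), [2, 1]
        )

    def test_no_events_all_zero(self):
        np.testing.assert_array_equal(
            count_deflections_windowed([], 27.0), [0, 0, 0, 0, 0]
        )

    def test_boundary_event_goes_to_later_window(self):
        events = [DeflectionEvent(5.0, -100.0, 50.0)]
        np.testing.assert_array_equal(count_deflections_windowed(events, 10.0), [0, 1])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        times=st.lists(st.floats(0.0, 99.99), min_size=0, max_size=60),
        window=st.sampled_from([2.0, 5.0, 10.0]),
    )
    def test_counts_conserve_events_in_covered_span(self, times, window):
        events = [DeflectionEvent(t, -100.0, 50.0) for t in sorted(times)]
        duration = 100.0
        counts = count_deflections_windowed(events, duration, window)
        span = counts.size * window
        assert counts.sum() == sum(1 for t in times if t < span)


class TestBouts:
    def test_regular_train_is_one_bout(self):
        events = [DeflectionEvent(1.0 + 0.5 * i, -100.0, 50.0) for i in range(10)]
        bouts = detect_oscillation_bouts(events)
        assert len(bouts) == 1
        assert bouts[0].f0_hz == pytest.approx(2.0)
        assert bouts[0].n_cycles == 10

    def test_two_events_no_bout(self):
        events = [DeflectionEvent(t, -100.0, 50.0) for t in (1.0, 1.5)]
        assert detect_oscillation_bouts(events) == []

    def test_long_gap_splits_runs(self):
        first = [DeflectionEvent(1.0 + 0.5 * i, -100.0, 50.0) for i in range(5)]
        second = [DeflectionEvent(14.0 + 0.5 * i, -100.0, 50.0) for i in range(5)]
        bouts = detect_oscillation_bouts(first + second)
        assert len(bouts) == 2
        assert all(b.n_cycles == 5 for b in bouts)


class TestPhaseLocking:
    def _events(self, period=0.5, n=2001):
        return [DeflectionEvent(i * period, -100.0, 50.0) for i in range(n)]

    def test_spikes_at_troughs_fully_locked(self):
        events = self._events(n=101)
        train = SpikeTrain(np.arange(1, 100) * 0.5, "c", 0.0, 0.0)
        res = phase_locking(train, events)
        assert res.vector_strength == pytest.approx(1.0, abs=1e-9)
        assert res.mean_phase_rad == pytest.approx(0.0, abs=1e-9)
        assert res.defined

    def test_uniform_phases_near_zero(self, rng):
        events = self._events()
        spikes = np.sort(rng.uniform(0.0, 1000.0, 1000))
        res = phase_locking(SpikeTrain(np.unique(spikes), "c", 0.0, 0.0), events)
        assert res.vector_strength < 0.06  # Rayleigh E|R| ~ sqrt(pi/4n)

    @pytest.mark.parametrize("sigma", [0.02, 0.05, 0.1, 0.2])
    def test_wrapped_gaussian_calibration(self, sigma, rng):
        """VS = exp(-(2 pi sigma)^2 / 2) for Gaussian phase jitter, within 0.03."""
        events = self._events()
        centers = rng.choice(np.arange(1, 2000) * 0.5, 20_000)
        spikes = np.unique(np.sort(centers + rng.normal(0.0, sigma * 0.5, 20_000)))
        res = phase_locking(SpikeTrain(spikes, "c", 0.0, 0.0), events)
        expected = np.exp(-((2 * np.pi * sigma) ** 2) / 2)
        assert abs(res.vector_strength - expected) < 0.03

    def test_too_few_spikes_flagged_undefined(self):
        events = self._events(n=10)
        res = phase_locking(SpikeTrain(np.array([1.1, 2.2]), "c", 0.0, 0.0), events)
        assert not res.defined

    def test_needs_two_events(self):
        with pytest.raises(ValueError):
            phase_locking(
                SpikeTrain(np.array([1.0]), "c", 0.0, 0.0),
                [DeflectionEvent(0.0, -1.0, 10.0)],
            )


class TestClassification:
    def test_oscillatory_preset_flagged_true(self):
        rec, _ = simulate_recording(make_preset("RCS_M19"), 60.0, seed=5)
        lfp = apply_filter(rec.channel(0), PLANAR_PROFILE.lfp, band=Band.LFP)
        assert classify_oscillatory(compute_spectrum(lfp))

    def test_wild_type_preset_flagged_false(self):
        rec, _ = simulate_recording(make_preset("WT_RAT"), 60.0, seed=5)
        lfp = apply_filter(rec.channel(0), PLANAR_PROFILE.lfp, band=Band.LFP)
        assert not classify_oscillatory(compute_spectrum(lfp))

    def test_flat_spectrum_false(self):
        spec = compute_spectrum(_lfp(np.full(int(20 * FS), 3.0)))
        assert not classify_oscillatory(spec)
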