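"""EEG filtering, artifact flagging, SO/spindle detection, spectra."""
import numpy as np
import pytest

from clasphase.eeg import (classify_stim_dependent_spindles,
                           compute_normalized_psd, detect_slow_oscillations,
                           detect_spindles, flag_eeg_artifacts,
                           psd_norm_constant, welch_psd_window,
                           zero_phase_bandpass, SlowOscillationEvent,
                           SpindleEvent)
from clasphase.simulate import one_over_f_noise, spindle_waveform, _add_at

FS = 256.0


def sine(freq, dur, amp=1.0, fs=FS):
    return amp * np.sin(2 * np.pi * freq * np.arange(int(dur * fs)) / fs)


class TestZeroPhaseBandpass:
    def test_in_band_tone_preserved_with_zero_lag(self):
        x = sine(2.0, 60.0)
        y = zero_phase_bandpass(x, 0.5, 4.0, FS)
        core = slice(int(5 * FS), int(55 * FS))
        assert np.abs(y[core]).max() == pytest.approx(1.0, rel=0.01)
        lags = np.arange(-20, 21)
        xc = [np.dot(x[core], np.roll(y, lag)[core]) for lag in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_out_of_band_tone_attenuated(self):
        x = sine(20.0, 60.0)
        y = zero_phase_bandpass(x, 0.5, 4.0, FS)
        core = slice(int(5 * FS), int(55 * FS))
        assert np.std(y[core]) < 0.05 * np.std(x[core])

    def test_dc_rejected(self):
        y = zero_phase_bandpass(np.full(int(60 * FS), 7.0), 0.1, 30.0, FS)
        assert np.abs(y).max() < 1e-3 * 7.0

    def test_band_edges_beyond_nyquist_raise(self):
        with pytest.raises(ValueError, match="Nyquist"):
            zero_phase_bandpass(np.zeros(1000), 0.5, 200.0, FS)


class TestArtifactFlagging:
    def test_large_excursion_flags_containing_segment(self, rng):
        x = rng.normal(0, 10, int(80 * FS))
        x[int(20.5 * FS)] = 2000.0
        mask = flag_eeg_artifacts(x, FS)
        seg = slice(int(16 * FS), int(24 * FS))
        assert mask[seg].all()
        assert not mask[: int(16 * FS)].any()

    def test_homogeneous_noise_unflagged(self, rng):
        mask = flag_eeg_artifacts(rng.normal(0, 10, int(800 * FS)), FS)
        assert not mask.any()

    def test_single_wild_segment_flagged_by_sd_rule(self, rng):
        x = rng.normal(0, 10, int(800 * FS))
        wild = slice(int(400 * FS), int(408 * FS))
        x[wild] = rng.normal(0, 1400, wild.stop - wild.start)
        x[wild] = np.clip(x[wild], -1499, 1499)   # amplitude rule stays silent
        mask = flag_eeg_artifacts(x, FS)
        assert mask[wild].all()
        flagged_segments = {i // int(8 * FS) for i in np.flatnonzero(mask)}
        assert flagged_segments == {50}


class TestSlowOscillationDetector:
    def test_sinusoid_event_geometry(self):
        x = sine(0.8, 10.0, amp=110.0)
        events = detect_slow_oscillations(x, FS)
        assert len(events) == 7
        for e in events:
            assert e.p2p_uv == pytest.approx(220.0, abs=2.0)
            assert e.duration_s == pytest.approx(1.25, abs=0.01)
            assert e.trough_uv < -80.0 and e.start_s < e.end_s

    def test_small_amplitude_rejected(self):
        assert detect_slow_oscillations(sine(0.8, 10.0, amp=60.0), FS) == []

    def test_trough_at_exact_threshold_rejected(self):
        # trough exactly -80.0 μV fails the strict "< -80" criterion even
        # though the peak-to-peak criterion passes
        t = np.arange(int(10 * FS)) / FS
        base = np.sin(2 * np.pi * 0.8 * t)
        x = np.where(base < 0, 80.0, 160.0) * base
        events = detect_slow_oscillations(x, FS)
        assert events == []
        x2 = np.where(base < 0, 81.0, 160.0) * base
        assert len(detect_slow_oscillations(x2, FS)) > 0

    def test_artifact_overlap_drops_event(self):
        x = sine(0.8, 10.0, amp=110.0)
        mask = np.zeros(len(x), dtype=bool)
        mask[int(2.0 * FS): int(2.2 * FS)] = True
        all_events = detect_slow_oscillations(x, FS)
        kept = detect_slow_oscillations(x, FS, artifact_mask=mask)
        assert len(kept) == len(all_events) - 1


class TestSpindleDetector:
    def make_trace(self, rng, bursts, dur_s=300.0, noise_sd=5.0, amp=30.0,
                   freq=13.0):
        n = int(dur_s * FS)
        x = one_over_f_noise(n, FS, 1.0, noise_sd, rng)
        for start, bdur in bursts:
            _add_at(x, int(start * FS), spindle_waveform(bdur, amp, freq, FS))
        sb = zero_phase_bandpass(x, 11.0, 16.0, FS)
        bb = zero_phase_bandpass(x, 0.1, 30.0, FS)
        return sb, bb, np.ones(n, dtype=bool)

    def test_hann_burst_detected_with_correct_geometry(self, rng):
        sb, bb, mask = self.make_trace(rng, [(s, 1.0) for s in
                                             np.arange(10, 290, 20.0)])
        events = detect_spindles(sb, bb, FS, mask)
        target = [e for e in events if abs(e.start_s - 50.0) < 0.5]
        assert len(target) == 1
        e = target[0]
        assert e.duration_s == pytest.approx(1.0, abs=0.15)
        assert e.n_oscillations >= 12
        assert e.peak_freq_hz == pytest.approx(13.0, abs=0.5)

    def test_too_short_burst_rejected(self, rng):
        # place the 0.2-s burst on a locally quiet stretch of the noise so
        # the episode is the burst alone, not a merge with a noise
        # excursion; modest amplitude keeps the band-pass ringing of the
        # 2.6-cycle burst from stretching the supra-threshold episode
        from clasphase.eeg import _rms_envelope
        n = int(300 * FS)
        noise = one_over_f_noise(n, FS, 1.0, 5.0, rng)
        env0 = _rms_envelope(zero_phase_bandpass(noise, 11.0, 16.0, FS),
                             FS, 0.2)
        thr0 = np.percentile(env0, 88.86)
        cands = np.arange(160.0, 290.0, 2.5)
        local_max = [env0[int((c - 1.0) * FS): int((c + 1.5) * FS)].max()
                     for c in cands]
        quiet = float(cands[int(np.argmin(local_max))])
        assert min(local_max) < thr0
        x = noise.copy()
        for s in np.arange(10, 145, 20.0):
            _add_at(x, int(s * FS), spindle_waveform(1.0, 30.0, 13.0, FS))
        _add_at(x, int(quiet * FS), spindle_waveform(0.2, 10.0, 13.0, FS))
        sb = zero_phase_bandpass(x, 11.0, 16.0, FS)
        bb = zero_phase_bandpass(x, 0.1, 30.0, FS)
        events = detect_spindles(sb, bb, FS, np.ones(n, dtype=bool))
        assert not any(abs(e.start_s - quiet) < 0.5 for e in events)
        assert any(abs(e.start_s - 50.0) < 0.5 for e in events)

    def test_out_of_band_burst_rejected(self, rng):
        n = int(300 * FS)
        x = one_over_f_noise(n, FS, 1.0, 5.0, rng)
        for s in np.arange(10, 270, 20.0):
            _add_at(x, int(s * FS), spindle_waveform(1.0, 30.0, 13.0, FS))
        _add_at(x, int(285.0 * FS), spindle_waveform(1.0, 30.0, 20.0, FS))
        sb = zero_phase_bandpass(x, 11.0, 16.0, FS)
        bb = zero_phase_bandpass(x, 0.1, 30.0, FS)
        events = detect_spindles(sb, bb, FS, np.ones(n, dtype=bool))
        assert not any(abs(e.start_s - 285.0) < 0.5 for e in events)

    def test_raising_percentile_never_increases_detections(self, rng):
        sb, bb, mask = self.make_trace(rng, [(s, 1.0) for s in
                                             np.arange(10, 290, 15.0)])
        n_default = len(detect_spindles(sb, bb, FS, mask, percentile=88.86))
        n_high = len(detect_spindles(sb, bb, FS, mask, percentile=95.0))
        assert n_high <= n_default

    def test_empty_deep_sleep_mask_raises(self, rng):
        sb, bb, mask = self.make_trace(rng, [], dur_s=60.0)
        with pytest.raises(ValueError, match="N2/N3"):
            detect_spindles(sb, bb, FS, np.zeros_like(mask))


class TestNormalizedPsd:
    def test_mean_total_power_over_stim_windows_is_one(self, rng):
        x = rng.normal(0, 20, int(200 * FS))
        wins = [(10.0 * k, 10.0 * k + 8.0) for k in range(1, 15)]
        ests = compute_normalized_psd(x, FS, wins, wins)
        total = np.mean([e.power.mean() for e in ests])
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_pure_tone_peak_on_grid(self, rng):
        x = sine(2.0, 40.0, amp=50.0) + rng.normal(0, 1, int(40 * FS))
        est = compute_normalized_psd(x, FS, [(2.0, 34.0)], [(2.0, 34.0)])[0]
        assert est.freqs[np.argmax(est.power)] == pytest.approx(2.0, abs=0.1)

    def test_swa_scales_with_variance(self, rng):
        x = np.r_[rng.normal(0, 10, int(400 * FS)),
                  rng.normal(0, 20, int(400 * FS))]
        wins = [(10.0, 390.0), (410.0, 790.0)]
        e1, e2 = compute_normalized_psd(x, FS, wins, wins)
        assert e2.swa / e1.swa == pytest.approx(4.0, rel=0.10)

    def test_normalization_is_idempotent(self, rng):
        x = rng.normal(0, 20, int(200 * FS))
        wins = [(10.0 * k, 10.0 * k + 8.0) for k in range(1, 15)]
        c1 = psd_norm_constant(x, FS, wins)
        renorm = psd_norm_constant(x / np.sqrt(c1), FS, wins)
        assert renorm == pytest.approx(1.0, rel=1e-9)

    def test_window_shorter_than_segment_raises(self, rng):
        x = rng.normal(0, 1, int(20 * FS))
        with pytest.raises(ValueError, match="shorter"):
            welch_psd_window(x, FS, (0.0, 2.0))


class TestStimDependentSpindles:
    so = SlowOscillationEvent(start_s=1.0, end_s=2.2, trough_s=1.4,
                              trough_uv=-100, peak_s=2.0, peak_uv=80,
                              p2p_uv=180, duration_s=1.2)

    def spindle(self, start):
        return SpindleEvent(start_s=start, end_s=start + 1.0, duration_s=1.0,
                            n_oscillations=12, peak_freq_hz=13.0, rms_peak=20.0)

    def test_spindle_after_trough_counts(self):
        assert classify_stim_dependent_spindles(
            [self.spindle(1.9)], self.so, window_end_s=11.4)

    def test_spindle_before_trough_does_not_count(self):
        assert not classify_stim_dependent_spindles(
            [self.spindle(1.3)], self.so, window_end_s=11.4)

    def test_likelihood_is_the_proportion_of_flagged_trials(self):
        flags = [classify_stim_dependent_spindles(
            [self.spindle(1.9)] if k < 3 else [], self.so, 11.4)
            for k in range(10)]
        assert np.mean(flags) == pytest.approx(0.3)
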