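"""Synthetic-cohort generator: determinism, injected structure, ground truth."""
import numpy as np
import pandas as pd
import pytest

from clasphase import ConfigError, SimConfig, generate_recording
from clasphase.config import AnalysisParams
from clasphase.ecg import derive_instantaneous_hr, detect_r_peaks
from clasphase.eeg import detect_slow_oscillations, zero_phase_bandpass
from clasphase.simulate import (evoked_amplitudes, make_hypnogram,
                                schedule_tones, simulate_trial_table)


def quiet_config(**kw):
    base = dict(n_subjects=1, duration_s=600.0, seed=3)
    base.update(kw)
    return SimConfig(**base)


class TestGenerateRecording:
    def test_bit_identical_given_seed_and_subject(self):
        cfg = quiet_config()
        r1, t1 = generate_recording(cfg, 0)
        r2, t2 = generate_recording(cfg, 0)
        np.testing.assert_array_equal(r1.eeg, r2.eeg)
        np.testing.assert_array_equal(r1.ecg, r2.ecg)
        np.testing.assert_array_equal(r1.tones, r2.tones)
        assert r1.hypnogram == r2.hypnogram
        pd.testing.assert_frame_equal(t1.tones, t2.tones)

    def test_subjects_differ(self):
        cfg = quiet_config(n_subjects=2)
        r1, _ = generate_recording(cfg, 0)
        r2, _ = generate_recording(cfg, 1)
        assert not np.array_equal(r1.eeg, r2.eeg)

    def test_subject_index_out_of_range(self):
        with pytest.raises(ConfigError, match="subject_index"):
            generate_recording(quiet_config(), 5)

    @pytest.mark.parametrize("field,value", [
        ("tone_interval_min", 40.0),       # >= max
        ("preferred_phase_so", 200.0),
        ("hr_mean", -5.0),
        ("spindle_freq", 20.0),
        ("noise_sd", -1.0),
    ])
    def test_invalid_config_names_field(self, field, value):
        cfg = quiet_config(**{field: value})
        with pytest.raises(ConfigError, match=field.split("_")[0]):
            generate_recording(cfg, 0)

    def test_nothing_injected_yields_no_detected_so(self, params):
        cfg = quiet_config(noise_sd=0.0, so_rate=0.0, spindle_rate=0.0,
                           evoked_base_amp=0.0, evoked_gain_so=0.0,
                           evoked_gain_lf=0.0, evoked_gain_hf=0.0,
                           evoked_spindle_base_prob=0.0,
                           evoked_spindle_gain_so=0.0)
        rec, truth = generate_recording(cfg, 0)
        # pure deterministic background: the 50 μV rhythm never reaches the
        # 140 μV peak-to-peak / -80 μV trough criteria
        so_band = zero_phase_bandpass(rec.eeg, 0.5, 4.0, rec.fs_eeg)
        assert detect_slow_oscillations(so_band, rec.fs_eeg) == []
        assert truth.so_events.empty

    def test_hypnogram_covers_recording_and_is_mostly_deep(self):
        rec, _ = generate_recording(quiet_config(duration_s=7200.0), 0)
        assert len(rec.hypnogram) == int(np.ceil(rec.duration_s / 30.0))
        deep = sum(s in ("N2", "N3") for s in rec.hypnogram)
        assert deep / len(rec.hypnogram) >= 0.6

    def test_every_tone_falls_in_deep_sleep(self):
        rec, _ = generate_recording(quiet_config(duration_s=3600.0), 0)
        for t in rec.tones:
            assert rec.hypnogram[int(t // 30.0)] in ("N2", "N3")

    def test_mean_heart_rate_matches_configuration(self):
        cfg = quiet_config(hr_mean=60.0, lf_amp=3.0, hf_amp=2.0,
                           evoked_hr_base_bpm=0.0, evoked_hr_gain_so=0.0)
        rec, _ = generate_recording(cfg, 0)
        ecg = zero_phase_bandpass(rec.ecg, 0.5, 35.0, rec.fs_ecg)
        hr = derive_instantaneous_hr(detect_r_peaks(ecg, rec.fs_ecg))
        assert abs(hr.hr_bpm.mean() - 60.0) < 0.5

    def test_hr_band_power_peaks_at_configured_frequencies(self):
        from scipy.signal import welch
        cfg = quiet_config(duration_s=1200.0, evoked_hr_base_bpm=0.0,
                           evoked_hr_gain_so=0.0)
        rec, _ = generate_recording(cfg, 0)
        ecg = zero_phase_bandpass(rec.ecg, 0.5, 35.0, rec.fs_ecg)
        hr = derive_instantaneous_hr(detect_r_peaks(ecg, rec.fs_ecg))
        f, p = welch(hr.hr_bpm - hr.hr_bpm.mean(), fs=10.0, nperseg=8192)
        for band, f0 in (((0.04, 0.15), cfg.lf_freq), ((0.15, 0.4), cfg.hf_freq)):
            m = (f >= band[0]) & (f <= band[1])
            assert abs(f[m][np.argmax(p[m])] - f0) <= 0.01

    def test_injected_so_events_are_recovered(self):
        cfg = quiet_config(noise_sd=5.0, so_amp_mean=180.0, so_amp_sd=10.0,
                           duration_s=900.0)
        rec, truth = generate_recording(cfg, 0)
        so_band = zero_phase_bandpass(rec.eeg, 0.5, 4.0, rec.fs_eeg)
        events = detect_slow_oscillations(so_band, rec.fs_eeg)
        troughs = np.array([e.trough_s for e in events])
        injected = truth.so_events["trough_s"].to_numpy()
        hits = sum(np.any(np.abs(troughs - t) < 0.25) for t in injected)
        assert hits / len(injected) >= 0.95


class TestScheduleTones:
    def test_interval_bounds_on_all_n3_night(self, rng):
        cfg = quiet_config(duration_s=3600.0)
        tones = schedule_tones(cfg, ["N3"] * 120, rng)
        assert 3600 / 30 <= len(tones) <= 3600 / 15
        gaps = np.diff(tones)
        assert np.all(gaps >= 15.0) and np.all(gaps <= 30.0)

    def test_wake_only_hypnogram_gives_no_tones(self, rng):
        with pytest.warns(UserWarning, match="no N2/N3"):
            tones = schedule_tones(quiet_config(), ["W"] * 100, rng)
        assert len(tones) == 0

    def test_gaps_within_contiguous_blocks_respect_interval_range(self, rng):
        # 50% N3 in two contiguous blocks: consecutive tones inside the same
        # block are consecutive uniform draws, so their gaps lie in [15, 30]
        hyp = ["N3"] * 120 + ["R"] * 120
        tones = schedule_tones(quiet_config(duration_s=7200.0), hyp, rng)
        in_block = tones[tones < 120 * 30.0]
        assert len(in_block) > 50
        assert np.all(np.diff(in_block) >= 15.0 - 1e-9)
        assert np.all(np.diff(in_block) <= 30.0 + 1e-9)


class TestAmplitudeLaw:
    def test_all_gains_zero_gives_base_amplitude(self):
        cfg = quiet_config(evoked_gain_so=0, evoked_gain_lf=0, evoked_gain_hf=0)
        amps = evoked_amplitudes([10.0], [50.0], [-40.0], cfg)
        assert amps[0] == pytest.approx(cfg.evoked_base_amp)

    def test_single_component_at_optimum(self):
        cfg = quiet_config(evoked_gain_lf=0, evoked_gain_hf=0)
        amps = evoked_amplitudes([cfg.preferred_phase_so], [0.0], [0.0], cfg)
        assert amps[0] == pytest.approx(cfg.evoked_base_amp + cfg.evoked_gain_so)

    def test_all_components_at_their_optima(self):
        cfg = quiet_config(evoked_gain_so=20.0, evoked_gain_lf=10.0,
                           evoked_gain_hf=10.0)
        amps = evoked_amplitudes([cfg.preferred_phase_so],
                                 [cfg.preferred_phase_lf],
                                 [cfg.preferred_phase_hf], cfg)
        assert amps[0] == pytest.approx(cfg.evoked_base_amp + 40.0)

    def test_regression_recovers_each_gain_within_one_percent(self, rng):
        cfg = quiet_config()
        n = 20000
        phi = rng.uniform(-180, 180, size=(n, 3))
        amps = evoked_amplitudes(phi[:, 0], phi[:, 1], phi[:, 2], cfg)
        X = np.column_stack([
            np.cos(np.radians(phi[:, 0] - cfg.preferred_phase_so)),
            np.cos(np.radians(phi[:, 1] - cfg.preferred_phase_lf)),
            np.cos(np.radians(phi[:, 2] - cfg.preferred_phase_hf)),
            np.ones(n)])
        beta = np.linalg.lstsq(X, amps, rcond=None)[0]
        for est, true in zip(beta[:3], (cfg.evoked_gain_so, cfg.evoked_gain_lf,
                                        cfg.evoked_gain_hf)):
            assert abs(est - true) / true < 0.01

    def test_ground_truth_amplitudes_obey_the_law(self):
        cfg = quiet_config()
        _, truth = generate_recording(cfg, 0)
        t = truth.tones
        expect = evoked_amplitudes(t.phi_so, t.phi_lf, t.phi_hf, cfg)
        np.testing.assert_allclose(t.evoked_amp_uv.to_numpy(), expect)


class TestTrialTable:
    def test_structure_and_determinism(self):
        cfg = quiet_config(n_subjects=3)
        t1 = simulate_trial_table(cfg, 50, 30, np.random.default_rng(7))
        t2 = simulate_trial_table(cfg, 50, 30, np.random.default_rng(7))
        pd.testing.assert_frame_equal(t1, t2)
        assert set(t1.subject_id.unique()) == {0, 1, 2}
        assert int(t1.is_stim.sum()) == 150
        assert ((t1.phi_so >= -180) & (t1.phi_so < 180)).all()

    def test_stim_responses_follow_the_amplitude_law_on_average(self):
        cfg = quiet_config(n_subjects=5)
        tab = simulate_trial_table(cfg, 400, 100, np.random.default_rng(11),
                                   resid_sd_uv=5.0)
        stim = tab[tab.is_stim]
        near = stim[np.abs((stim.phi_so - 75 + 180) % 360 - 180) < 20]
        far = stim[np.abs((stim.phi_so + 105 + 180) % 360 - 180) < 20]
        assert near.so_p2p_uv.mean() - far.so_p2p_uv.mean() > 25
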