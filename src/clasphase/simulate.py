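"""Synthetic polysomnography cohort with known phase-dependent evoked responses.

Each subject gets one EEG channel (1/f background + a continuous ~0.8 Hz
slow rhythm + discrete slow-oscillation events + spindle bursts, μV), one
ECG channel (template beats on an RR train modulated by LF and HF
heart-rate oscillations, mV), a 30-s-epoch hypnogram, arousal intervals,
and a tone train at random 15-30 s intervals restricted to N2/N3.

Slow-oscillation events are biphasic trough-then-peak waveforms.  While an
event plays out, the background rhythm is suppressed (phase reset), so the
measured peak-to-peak amplitude of an event reflects its injected
amplitude rather than chance alignment with the rhythm; injected
amplitudes are pre-compensated for the peak-to-peak attenuation of the
0.5-4 Hz zero-phase band-pass the detector operates on.  Tone-evoked
events start a fixed latency after onset, and their amplitude follows the
additive cosine law

    A = base + g_so·cos(φ_so − φ*_so) + g_lf·cos(φ_lf − φ*_lf)
             + g_hf·cos(φ_hf − φ*_hf)        (clipped at 0)

where the φ are the true (analytic, noise-free) phases of the three
oscillations at tone onset.  Every injected element is recorded in a
GroundTruth manifest.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ConfigError, SimConfig

__all__ = [
    "Recording",
    "GroundTruth",
    "generate_recording",
    "generate_cohort",
    "schedule_tones",
    "inject_evoked_responses",
    "evoked_amplitudes",
    "so_waveform",
    "spindle_waveform",
    "simulate_trial_table",
    "STAGES",
]

STAGES = ("W", "N1", "N2", "N3", "R")
NREM_DEEP = ("N2", "N3")
EPOCH_S = 30.0
SO_BAND = (0.5, 4.0)      # detection band the amplitude compensation targets


@dataclass
class Recording:
    """One subject's synchronized signals and annotations."""

    subject_id: int
    fs_eeg: float
    fs_ecg: float
    eeg: np.ndarray           # μV
    ecg: np.ndarray           # mV
    hypnogram: List[str]      # stage per 30-s epoch
    arousals: np.ndarray      # (n, 2) [start_s, end_s]
    tones: np.ndarray         # onset_s

    @property
    def duration_s(self) -> float:
        return len(self.eeg) / self.fs_eeg


@dataclass
class GroundTruth:
    """Everything the generator injected, for recovery scoring."""

    subject_id: int
    so_events: pd.DataFrame       # start_s, duration_s, trough_s, p2p_uv
    spindles: pd.DataFrame        # start_s, duration_s, freq_hz
    tones: pd.DataFrame           # onset_s, phi_so, phi_lf, phi_hf,
    #                               evoked_amp_uv, evoked_trough_s,
    #                               spindle_injected, hr_amp_bpm
    lf_phase0_deg: float = 0.0
    hf_phase0_deg: float = 0.0
    so_phase0_deg: float = 0.0


def _rng_for(config: SimConfig, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(config.seed) % (2**31), int(subject_index)])
    )


def wrap_deg(phi):
    """Wrap degrees into [-180, 180)."""
    return (np.asarray(phi, dtype=float) + 180.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def make_hypnogram(n_epochs: int, rng: np.random.Generator) -> List[str]:
    """Block-structured night: brief wake/N1, long N2/N3 runs, some REM.

    Not a model of real sleep architecture; it guarantees >= 60% N2/N3 and
    provides stage boundaries for the selection logic to trip over.
    """
    blocks = [("W", 1), ("N1", 2)]
    while sum(n for _, n in blocks) < n_epochs:
        blocks += [
            ("N2", int(rng.integers(8, 15))),
            ("N3", int(rng.integers(12, 21))),
            ("N2", int(rng.integers(4, 9))),
            ("R", int(rng.integers(4, 9))),
            ("N1", int(rng.integers(1, 3))),
        ]
    stages: List[str] = []
    for stage, n in blocks:
        stages.extend([stage] * n)
    return stages[:n_epochs]


def make_arousals(duration_s: float, hypnogram: List[str], rate_per_h: float,
                  rng: np.random.Generator) -> np.ndarray:
    n = rng.poisson(rate_per_h * duration_s / 3600.0)
    starts = np.sort(rng.uniform(0, max(duration_s - 15.0, 1.0), size=n))
    durs = rng.uniform(5.0, 15.0, size=n)
    out = [(s, min(s + d, duration_s)) for s, d in zip(starts, durs)
           if hypnogram[min(int(s // EPOCH_S), len(hypnogram) - 1)] != "W"]
    return np.array(out, dtype=float).reshape(-1, 2)


def schedule_tones(config: SimConfig, hypnogram: List[str],
                   rng: np.random.Generator) -> np.ndarray:
    """Tone onsets at uniform random intervals, dropped outside N2/N3."""
    if len(hypnogram) == 0:
        raise ValueError("hypnogram must be nonempty")
    duration_s = len(hypnogram) * EPOCH_S
    if not any(s in NREM_DEEP for s in hypnogram):
        warnings.warn("hypnogram contains no N2/N3 epochs; no tones scheduled")
        return np.array([], dtype=float)
    onsets = []
    t = 0.0
    while True:
        t += rng.uniform(config.tone_interval_min, config.tone_interval_max)
        if t >= duration_s:
            break
        epoch = int(t // EPOCH_S)
        if hypnogram[epoch] in NREM_DEEP:
            onsets.append(t)
    return np.array(onsets, dtype=float)


def one_over_f_noise(n: int, fs: float, slope: float, sd: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with power spectral density ∝ 1/f^slope, scaled to sd."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-slope / 2.0)
    x = np.fft.irfft(spec * shaping, n=n)
    s = x.std()
    return x * (sd / s) if s > 0 else x


SO_TROUGH_FRAC = 0.5 - 0.144   # trough position as a fraction of duration


def so_waveform(duration_s: float, p2p_uv: float, fs: float) -> np.ndarray:
    """One biphasic slow-oscillation cycle: trough first, then peak.

    A Gaussian-derivative (K-complex-like) shape whose spectrum sits well
    inside the 0.5-4 Hz detection band, asymmetrized (55% trough / 45%
    peak of the peak-to-peak amplitude) so events above the 140 μV
    criterion also clear the -80 μV trough criterion.  The trough falls at
    SO_TROUGH_FRAC·duration, the peak symmetrically after the midpoint.
    """
    n = max(int(round(duration_s * fs)), 8)
    t = (np.arange(n) - n / 2) / n
    g = t * np.exp(-0.5 * (t / 0.144) ** 2)     # trough at -0.144, peak at +0.144
    g = g / (g.max() - g.min())
    return p2p_uv * np.where(g < 0, 1.1, 0.9) * g


def spindle_waveform(duration_s: float, amp_uv: float, freq_hz: float,
                     fs: float, phase0: float = 0.0) -> np.ndarray:
    n = max(int(round(duration_s * fs)), 4)
    t = np.arange(n) / fs
    return amp_uv * np.hanning(n) * np.sin(2 * np.pi * freq_hz * t + phase0)


def _add_at(signal: np.ndarray, start_idx: int, wave: np.ndarray) -> None:
    a = max(start_idx, 0)
    b = min(start_idx + len(wave), len(signal))
    if b > a:
        signal[a:b] += wave[a - start_idx: b - start_idx]


def _poisson_events(rate_per_min: float, duration_s: float, hypnogram: List[str],
                    rng: np.random.Generator, refractory_s: float) -> np.ndarray:
    """Event start times at the given rate, restricted to N2/N3 epochs."""
    if rate_per_min <= 0:
        return np.array([], dtype=float)
    t, out = 0.0, []
    while t < duration_s:
        t += rng.exponential(60.0 / rate_per_min) + refractory_s
        if t >= duration_s:
            break
        if hypnogram[int(t // EPOCH_S)] in NREM_DEEP:
            out.append(t)
    return np.array(out, dtype=float)


def evoked_amplitudes(phi_so, phi_lf, phi_hf, config: SimConfig) -> np.ndarray:
    """The additive cosine amplitude law, clipped at 0 from below (μV)."""
    amps = (config.evoked_base_amp
            + config.evoked_gain_so * np.cos(np.radians(np.asarray(phi_so, dtype=float) - config.preferred_phase_so))
            + config.evoked_gain_lf * np.cos(np.radians(np.asarray(phi_lf, dtype=float) - config.preferred_phase_lf))
            + config.evoked_gain_hf * np.cos(np.radians(np.asarray(phi_hf, dtype=float) - config.preferred_phase_hf)))
    return np.clip(amps, 0.0, None)


@lru_cache(maxsize=64)
def _band_attenuation(fs: float, duration_s: float) -> float:
    """Peak-to-peak attenuation of one SO waveform under the zero-phase
    0.5-4 Hz band-pass; injected amplitudes are divided by this so the
    band-limited detector reads the nominal amplitude."""
    from .eeg import zero_phase_bandpass
    n = int(30 * fs)
    x = np.zeros(n)
    _add_at(x, n // 2, so_waveform(duration_s, 2.0, fs))
    y = zero_phase_bandpass(x, SO_BAND[0], SO_BAND[1], fs)
    mid = slice(n // 2 - int(fs), n // 2 + int(round((duration_s + 1) * fs)))
    return float((y[mid].max() - y[mid].min()) / 2.0)


def _suppression_envelope(n: int, fs: float,
                          windows: Sequence[Tuple[float, float]],
                          ramp_s: float = 0.15) -> np.ndarray:
    """Multiplicative envelope modeling phase reset of the ongoing rhythm:
    zero while each slow-oscillation event plays out, cosine ramps at the
    edges."""
    env = np.ones(n)
    ra = max(int(round(ramp_s * fs)), 1)
    down = 0.5 * (1 + np.cos(np.pi * np.arange(ra) / ra))
    for a, b in windows:
        ia, ib = int(round(a * fs)), int(round(b * fs))
        lo, hi = max(ia, 0), min(ib, n)
        if hi > lo:
            env[lo:hi] = 0.0
        for s0, ramp in ((ia - ra, down), (ib, down[::-1])):
            a0, b0 = max(s0, 0), min(s0 + ra, n)
            if b0 > a0:
                env[a0:b0] = np.minimum(env[a0:b0], ramp[a0 - s0: b0 - s0])
    return env


def inject_evoked_responses(eeg: np.ndarray, tones: np.ndarray,
                            amps_uv: np.ndarray, config: SimConfig,
                            fs: float) -> np.ndarray:
    """Add one evoked SO cycle per tone at onset + evoked_latency_s.

    ``amps_uv`` are the ground-truth peak-to-peak amplitudes (already
    clipped at 0); waveforms are pre-compensated for the detection band's
    attenuation.  Returns a new array.
    """
    out = eeg.copy()
    dur = 1.0 / config.so_freq
    alpha = _band_attenuation(fs, dur)
    for onset, amp in zip(tones, amps_uv):
        if amp <= 0:
            continue
        idx = int(round((onset + config.evoked_latency_s) * fs))
        _add_at(out, idx, so_waveform(dur, amp / alpha, fs))
    return out


# ---------------------------------------------------------------------------
# full recording
# ---------------------------------------------------------------------------

def _ecg_template(fs: float) -> Tuple[np.ndarray, int]:
    """Template beat: narrow R spike plus small Q/S/T deflections (mV)."""
    t = np.arange(-0.1, 0.4, 1.0 / fs)
    wave = (1.0 * np.exp(-0.5 * (t / 0.008) ** 2)
            - 0.10 * np.exp(-0.5 * ((t + 0.025) / 0.010) ** 2)
            - 0.15 * np.exp(-0.5 * ((t - 0.025) / 0.010) ** 2)
            + 0.20 * np.exp(-0.5 * ((t - 0.25) / 0.05) ** 2))
    r_idx = int(np.argmax(wave))
    return wave, r_idx


def _beat_times(config: SimConfig, duration_s: float, hr_of_t) -> np.ndarray:
    """Integrate RR intervals with RR anchored at the interval's *end* beat.

    Solving t_next = t + 60/HR(t_next) by fixed point makes the analysis
    convention (HR assigned at interval end beats) exact: 60/RR equals the
    modulating HR at the beat instant.
    """
    beats = [0.5]
    t = 0.5
    while True:
        t_next = t + 60.0 / hr_of_t(t)
        for _ in range(3):
            t_next = t + 60.0 / hr_of_t(t_next)
        if t_next >= duration_s - 0.5:
            break
        beats.append(t_next)
        t = t_next
    return np.array(beats)


def generate_recording(config: SimConfig,
                       subject_index: int) -> Tuple[Recording, GroundTruth]:
    """Deterministically synthesize one subject given (config.seed, subject_index)."""
    config.validate()
    if subject_index >= config.n_subjects:
        raise ConfigError(
            f"subject_index {subject_index} >= n_subjects {config.n_subjects}")
    rng = _rng_for(config, subject_index)
    fs = config.fs_eeg
    n = int(round(config.duration_s * fs))
    t_eeg = np.arange(n) / fs
    n_epochs = int(np.ceil(config.duration_s / EPOCH_S))

    hypnogram = make_hypnogram(n_epochs, rng)
    arousals = make_arousals(config.duration_s, hypnogram,
                             config.arousal_rate_per_h, rng)
    tones = schedule_tones(config, hypnogram, rng)

    # --- EEG: background + rhythm + discrete SO events -------------------
    background = one_over_f_noise(n, fs, config.background_slope,
                                  config.noise_sd, rng)
    so_phase0 = float(rng.uniform(0, 360.0))
    rhythm = config.so_rhythm_amp * np.sin(
        2 * np.pi * config.so_freq * t_eeg + np.radians(so_phase0))

    period = 1.0 / config.so_freq
    evoked_guard = config.evoked_latency_s + period + 0.6
    so_track = np.zeros(n)
    suppression: List[Tuple[float, float]] = []
    so_rows = []
    # spontaneous SOs: duration-jittered waveforms kept clear of the tones'
    # evoked windows (refractoriness), so evoked amplitudes stay clean
    dur_grid = np.round(np.linspace(0.8, 1.4, 13), 3)
    for start in _poisson_events(config.so_rate, config.duration_s - 2.0,
                                 hypnogram, rng, refractory_s=1.5):
        dur = float(rng.choice(dur_grid))
        if len(tones):
            # SO spans [start, start+dur]; evoked window [tone, tone+guard]
            rel = tones - start
            if np.any((rel > -(evoked_guard + 0.3)) & (rel < dur + 0.3)):
                continue
        amp = max(rng.normal(config.so_amp_mean, config.so_amp_sd), 0.0)
        _add_at(so_track, int(round(start * fs)),
                so_waveform(dur, amp / _band_attenuation(fs, dur), fs))
        suppression.append((start, start + dur))
        so_rows.append((start, dur, start + SO_TROUGH_FRAC * dur, amp))
    so_events = pd.DataFrame(
        so_rows, columns=["start_s", "duration_s", "trough_s", "p2p_uv"])

    spindle_track = np.zeros(n)
    sp_rows = []
    # spontaneous spindles keep clear of tone response windows so STIM and
    # UNSTIM spindle baselines match; only the evoked coupling differs
    spindle_guard = 10.5
    for start in _poisson_events(config.spindle_rate, config.duration_s - 2.0,
                                 hypnogram, rng, refractory_s=1.0):
        dur = rng.uniform(0.5, 1.5)
        if len(tones):
            rel = start - tones
            if np.any((rel > -(dur + 0.2)) & (rel < spindle_guard)):
                continue
        _add_at(spindle_track, int(round(start * fs)),
                spindle_waveform(dur, config.spindle_amp, config.spindle_freq,
                                 fs, rng.uniform(0, 2 * np.pi)))
        sp_rows.append((start, dur, config.spindle_freq))

    # --- true phases at tone onsets (analytic, noise-free) ---------------
    lf_phase0 = float(rng.uniform(0, 360.0))
    hf_phase0 = float(rng.uniform(0, 360.0))
    phi_so = wrap_deg(360.0 * config.so_freq * tones + so_phase0)
    phi_lf = wrap_deg(360.0 * config.lf_freq * tones + lf_phase0)
    phi_hf = wrap_deg(360.0 * config.hf_freq * tones + hf_phase0)

    amps = evoked_amplitudes(phi_so, phi_lf, phi_hf, config)
    if config.evoked_amp_sd > 0 and len(amps):
        amps = np.clip(amps + rng.normal(0, config.evoked_amp_sd, len(amps)),
                       0.0, None)
    evoked_trough = tones + config.evoked_latency_s + SO_TROUGH_FRAC * period
    for onset in tones:
        suppression.append((onset + config.evoked_latency_s,
                            onset + config.evoked_latency_s + period))

    env = _suppression_envelope(n, fs, suppression)
    eeg = background + rhythm * env + so_track + spindle_track
    eeg = inject_evoked_responses(eeg, tones, amps, config, fs)

    # --- tone-evoked spindles (probability coupled to SO phase only) ------
    p_sp = np.clip(config.evoked_spindle_base_prob
                   + config.evoked_spindle_gain_so
                   * np.cos(np.radians(phi_so - config.preferred_phase_so)),
                   0.0, 1.0) if len(tones) else np.array([])
    spindle_injected = (rng.uniform(size=len(tones)) < p_sp) if len(tones) \
        else np.array([], dtype=bool)
    for k in np.flatnonzero(spindle_injected):
        start = evoked_trough[k] + rng.uniform(0.2, 0.6)
        dur = rng.uniform(0.7, 1.2)
        _add_at(eeg, int(round(start * fs)),
                spindle_waveform(dur, config.spindle_amp, config.spindle_freq,
                                 fs, rng.uniform(0, 2 * np.pi)))
        sp_rows.append((start, dur, config.spindle_freq))
    spindles = pd.DataFrame(sp_rows, columns=["start_s", "duration_s", "freq_hz"])

    # --- ECG --------------------------------------------------------------
    hr_amp = (config.evoked_hr_base_bpm
              + config.evoked_hr_gain_so
              * np.cos(np.radians(phi_so - config.preferred_phase_hr_so))) \
        if len(tones) else np.array([])

    lf0, hf0 = np.radians(lf_phase0), np.radians(hf_phase0)

    def hr_of_t(t: float) -> float:
        hr = (config.hr_mean
              + config.lf_amp * np.sin(2 * np.pi * config.lf_freq * t + lf0)
              + config.hf_amp * np.sin(2 * np.pi * config.hf_freq * t + hf0))
        if len(tones):
            dt = t - tones - config.evoked_latency_s
            active = (dt > 0) & (dt < 4.0)
            if np.any(active):
                hr += np.sum(hr_amp[active] * np.sin(np.pi * dt[active] / 4.0))
        return max(hr, 20.0)

    beats = _beat_times(config, config.duration_s, hr_of_t)
    n_ecg = int(round(config.duration_s * config.fs_ecg))
    ecg = (rng.standard_normal(n_ecg) * config.ecg_noise_mv
           if config.ecg_noise_mv > 0 else np.zeros(n_ecg))
    template, r_idx = _ecg_template(config.fs_ecg)
    for b in beats:
        _add_at(ecg, int(round(b * config.fs_ecg)) - r_idx, template)

    tone_df = pd.DataFrame({
        "onset_s": tones,
        "phi_so": phi_so, "phi_lf": phi_lf, "phi_hf": phi_hf,
        "evoked_amp_uv": amps,
        "evoked_trough_s": evoked_trough,
        "spindle_injected": spindle_injected,
        "hr_amp_bpm": hr_amp,
    })
    rec = Recording(subject_id=subject_index, fs_eeg=fs, fs_ecg=config.fs_ecg,
                    eeg=eeg, ecg=ecg, hypnogram=hypnogram, arousals=arousals,
                    tones=tones)
    truth = GroundTruth(subject_id=subject_index, so_events=so_events,
                        spindles=spindles, tones=tone_df,
                        lf_phase0_deg=lf_phase0, hf_phase0_deg=hf_phase0,
                        so_phase0_deg=so_phase0)
    return rec, truth


def generate_cohort(config: SimConfig):
    """Yield (Recording, GroundTruth) for every subject."""
    for i in range(config.n_subjects):
        yield generate_recording(config, i)


# ---------------------------------------------------------------------------
# trial-level generator
# ---------------------------------------------------------------------------

def simulate_trial_table(config: SimConfig, n_stim: int, n_unstim: int,
                         rng: np.random.Generator,
                         resid_sd_uv: float = 25.0,
                         swa_gain_per_uv: float = 0.002,
                         swa_sd: float = 0.1) -> pd.DataFrame:
    """Draw a cohort of tone trials directly from the response model.

    Skips waveform synthesis and detection: onset phases are uniform on the
    circle, STIM responses follow the amplitude law plus Gaussian residuals,
    UNSTIM responses are phase-independent spontaneous amplitudes.  Useful
    for calibrating the statistics at many seeds.
    """
    config.validate()
    rows = []
    for subj in range(config.n_subjects):
        for is_stim, n_tr in ((True, n_stim), (False, n_unstim)):
            phi = rng.uniform(-180.0, 180.0, size=(n_tr, 3))
            if is_stim:
                amp = evoked_amplitudes(phi[:, 0], phi[:, 1], phi[:, 2], config)
                p_sp = np.clip(config.evoked_spindle_base_prob
                               + config.evoked_spindle_gain_so
                               * np.cos(np.radians(phi[:, 0] - config.preferred_phase_so)),
                               0, 1)
                hr_amp = (config.evoked_hr_base_bpm
                          + config.evoked_hr_gain_so
                          * np.cos(np.radians(phi[:, 0] - config.preferred_phase_hr_so)))
            else:
                amp = np.full(n_tr, config.so_amp_mean)
                p_sp = np.full(n_tr, config.evoked_spindle_base_prob)
                hr_amp = np.zeros(n_tr)
            so_p2p = np.clip(amp + rng.normal(0, resid_sd_uv, n_tr), 0, None)
            swa = (1.0 + swa_gain_per_uv * (so_p2p - config.so_amp_mean)
                   + rng.normal(0, swa_sd, n_tr))
            rows.append(pd.DataFrame({
                "subject_id": subj,
                "is_stim": is_stim,
                "phi_so": phi[:, 0], "phi_lf": phi[:, 1], "phi_hf": phi[:, 2],
                "so_p2p_uv": so_p2p,
                "swa_norm": swa,
                "spindle": rng.uniform(size=n_tr) < p_sp,
                "hr_p2p_bpm": np.clip(2.0 + hr_amp + rng.normal(0, 0.3, n_tr),
                                      0, None),
            }))
    return pd.concat(rows, ignore_index=True)
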