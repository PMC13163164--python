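"""EEG preprocessing: zero-phase filtering, artifact flagging, slow-oscillation
and spindle detection, and normalized Welch spectra (slow-wave activity).

Detection criteria
------------------
Slow oscillations are waves between two successive downward (positive to
negative) zero crossings of the 0.5-4 Hz signal with a trough below -80 μV
(strict), a peak-to-peak amplitude above 140 μV (strict), and a duration of
0.25-2.5 s (inclusive).

Spindles are intervals where the 0.2-s RMS envelope of the 11-16 Hz signal
exceeds the 88.86th percentile of N2/N3 artifact-free envelope values,
lasting 0.3-3 s, containing at least five full oscillation cycles, with a
unimodal Morlet-wavelet spectral peak inside 11-16 Hz and all 16-20 Hz
power strictly below that peak.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import butter, sosfiltfilt, welch

__all__ = [
    "FilteredEEG", "SlowOscillationEvent", "SpindleEvent", "SpectralEstimate",
    "zero_phase_bandpass", "flag_eeg_artifacts", "detect_slow_oscillations",
    "detect_spindles", "morlet_spectrum", "compute_normalized_psd",
    "classify_stim_dependent_spindles", "filter_eeg",
]


@dataclass
class SlowOscillationEvent:
    start_s: float
    end_s: float
    trough_s: float
    trough_uv: float
    peak_s: float
    peak_uv: float
    p2p_uv: float
    duration_s: float


@dataclass
class SpindleEvent:
    start_s: float
    end_s: float
    duration_s: float
    n_oscillations: int
    peak_freq_hz: float
    rms_peak: float


@dataclass
class FilteredEEG:
    fs: float
    broadband: np.ndarray
    so_band: np.ndarray
    spindle_band: np.ndarray
    artifact_mask: np.ndarray


@dataclass
class SpectralEstimate:
    freqs: np.ndarray
    power: np.ndarray
    swa: float
    norm_constant: float


def zero_phase_bandpass(signal: np.ndarray, low_hz: float, high_hz: float,
                        fs: float, order: int = 4) -> np.ndarray:
    """Forward-backward Butterworth band-pass (zero net phase shift)."""
    nyq = fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < {low_hz} < {high_hz} < Nyquist {nyq}")
    sos = butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, signal)


def filter_eeg(eeg: np.ndarray, fs: float, broadband=(0.1, 30.0),
               so_band=(0.5, 4.0), spindle_band=(11.0, 16.0),
               order: int = 4, artifact_kwargs: Optional[dict] = None) -> FilteredEEG:
    """Standard three-band decomposition plus the artifact mask."""
    bb = zero_phase_bandpass(eeg, *broadband, fs, order)
    mask = flag_eeg_artifacts(bb, fs, **(artifact_kwargs or {}))
    return FilteredEEG(
        fs=fs,
        broadband=bb,
        so_band=zero_phase_bandpass(eeg, *so_band, fs, order),
        spindle_band=zero_phase_bandpass(eeg, *spindle_band, fs, order),
        artifact_mask=mask,
    )


def flag_eeg_artifacts(broadband: np.ndarray, fs: float, segment_s: float = 8.0,
                       amp_limit_uv: float = 1500.0,
                       sd_z: float = 10.0) -> np.ndarray:
    """Per-sample artifact mask from amplitude and segment-SD rules.

    A segment is flagged if any sample exceeds ±amp_limit_uv, or if its SD
    has a z-score above ``sd_z`` relative to the across-segment SD
    distribution.  The z-score uses robust (median/MAD) location and scale:
    with a plain mean/SD the score of one extreme segment among n is
    bounded by ~sqrt(n) and a single gross artifact could never reach the
    threshold.
    """
    n = len(broadband)
    if n == 0:
        raise ValueError("signal must be nonempty")
    seg_len = max(int(round(segment_s * fs)), 1)
    n_seg = int(np.ceil(n / seg_len))
    mask = np.zeros(n, dtype=bool)
    sds = np.empty(n_seg)
    flagged_amp = np.zeros(n_seg, dtype=bool)
    for i in range(n_seg):
        seg = broadband[i * seg_len:(i + 1) * seg_len]
        sds[i] = seg.std()
        flagged_amp[i] = bool(np.any(np.abs(seg) > amp_limit_uv))
    scale = 1.4826 * np.median(np.abs(sds - np.median(sds)))
    if scale == 0:
        scale = sds.std()
    if scale > 0 and n_seg > 1:
        z = (sds - np.median(sds)) / scale
        flagged = flagged_amp | (z > sd_z)
    else:
        flagged = flagged_amp
    for i in np.flatnonzero(flagged):
        mask[i * seg_len:(i + 1) * seg_len] = True
    return mask


def detect_slow_oscillations(so_band: np.ndarray, fs: float,
                             artifact_mask: Optional[np.ndarray] = None,
                             trough_max_uv: float = -80.0,
                             p2p_min_uv: float = 140.0,
                             dur_min_s: float = 0.25,
                             dur_max_s: float = 2.5) -> List[SlowOscillationEvent]:
    """Slow oscillations between successive downward zero crossings.

    Amplitude criteria are strict inequalities; duration bounds inclusive.
    Events overlapping the artifact mask are dropped.  The returned list is
    sorted by start time and non-overlapping by construction.
    """
    x = np.asarray(so_band, dtype=float)
    # downward crossing at index i: x[i-1] > 0 and x[i] <= 0
    down = np.flatnonzero((x[:-1] > 0) & (x[1:] <= 0)) + 1
    events: List[SlowOscillationEvent] = []
    for a, b in zip(down[:-1], down[1:]):
        dur = (b - a) / fs
        if not (dur_min_s <= dur <= dur_max_s):
            continue
        seg = x[a:b]
        i_tr = int(np.argmin(seg))
        i_pk = int(np.argmax(seg))
        trough = seg[i_tr]
        peak = seg[i_pk]
        if not (trough < trough_max_uv and (peak - trough) > p2p_min_uv):
            continue
        if artifact_mask is not None and np.any(artifact_mask[a:b]):
            continue
        events.append(SlowOscillationEvent(
            start_s=a / fs, end_s=b / fs,
            trough_s=(a + i_tr) / fs, trough_uv=float(trough),
            peak_s=(a + i_pk) / fs, peak_uv=float(peak),
            p2p_uv=float(peak - trough), duration_s=dur))
    return events


def _rms_envelope(x: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    w = max(int(round(window_s * fs)), 1)
    kernel = np.ones(w) / w
    return np.sqrt(np.convolve(x * x, kernel, mode="same"))


def morlet_spectrum(signal: np.ndarray, fs: float, start: int, stop: int,
                    freqs_hz: np.ndarray, n_cycles: float = 6.0) -> np.ndarray:
    """Mean squared magnitude of complex Morlet coefficients over [start, stop).

    The wavelet at frequency f has a Gaussian envelope of SD
    n_cycles / (2π f) seconds.  The segment is evaluated with surrounding
    context so edge effects do not bias the event-average.
    """
    out = np.empty(len(freqs_hz))
    for k, f in enumerate(freqs_hz):
        sigma_t = n_cycles / (2 * np.pi * f)
        half = int(np.ceil(3 * sigma_t * fs))
        t = np.arange(-half, half + 1) / fs
        wavelet = np.exp(2j * np.pi * f * t) * np.exp(-0.5 * (t / sigma_t) ** 2)
        wavelet /= np.sqrt((np.abs(wavelet) ** 2).sum())
        a = max(start - half, 0)
        b = min(stop + half, len(signal))
        coef = np.convolve(signal[a:b], wavelet, mode="same")
        out[k] = float(np.mean(np.abs(coef[start - a: stop - a]) ** 2))
    return out


def _unimodal_in_band(spec: np.ndarray, freqs: np.ndarray,
                      band=(11.0, 16.0), high=(16.0, 20.0)) -> Tuple[bool, float]:
    """Exactly one strict interior local maximum inside ``band``, with every
    grid point above ``band`` strictly below it."""
    interior = np.flatnonzero(
        (spec[1:-1] > spec[:-2]) & (spec[1:-1] > spec[2:])) + 1
    in_band = [i for i in interior if band[0] <= freqs[i] <= band[1]]
    if len(in_band) != 1:
        return False, np.nan
    i_pk = in_band[0]
    high_mask = (freqs > high[0]) & (freqs <= high[1])
    if np.any(spec[high_mask] >= spec[i_pk]):
        return False, np.nan
    return True, float(freqs[i_pk])


def detect_spindles(spindle_band: np.ndarray, broadband: np.ndarray, fs: float,
                    n2n3_mask: np.ndarray,
                    artifact_mask: Optional[np.ndarray] = None,
                    percentile: float = 88.86, rms_window_s: float = 0.2,
                    dur_min_s: float = 0.3, dur_max_s: float = 3.0,
                    min_oscillations: int = 5,
                    threshold: Optional[float] = None) -> List[SpindleEvent]:
    """Sleep spindles from the RMS-envelope percentile threshold.

    The threshold is computed once per subject over all artifact-free N2/N3
    samples (or taken from ``threshold`` when the detector was calibrated
    on another record).  Candidates are maximal supra-threshold runs lying
    wholly in clean N2/N3; they must pass duration, cycle-count, and the
    Morlet unimodality check on the broadband signal.
    """
    x = np.asarray(spindle_band, dtype=float)
    env = _rms_envelope(x, fs, rms_window_s)
    clean = np.asarray(n2n3_mask, dtype=bool)
    if artifact_mask is not None:
        clean = clean & ~np.asarray(artifact_mask, dtype=bool)
    if not np.any(clean):
        raise ValueError("no artifact-free N2/N3 samples: threshold undefined")
    if threshold is None:
        threshold = np.percentile(env[clean], percentile)

    above = (env > threshold) & clean
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        stops = np.r_[stops, len(above)]

    wavelet_freqs = np.arange(10.0, 20.0 + 1e-9, 0.5)
    # the 0.2-s smoothing extends each supra-threshold episode outward, so
    # event boundaries are refined with a short (~one spindle cycle) RMS
    # window inside the episode; cycle counting and the spectral check use
    # the full episode
    env_short = _rms_envelope(x, fs, rms_window_s / 5.0)
    events: List[SpindleEvent] = []
    for a, b in zip(starts, stops):
        # maximal contiguous short-envelope run through the episode's peak
        p = a + int(np.argmax(env_short[a:b]))
        if env_short[p] < threshold:
            continue
        ra, rb = p, p + 1
        while ra > a and env_short[ra - 1] >= threshold:
            ra -= 1
        while rb < b and env_short[rb] >= threshold:
            rb += 1
        dur = (rb - ra) / fs
        if not (dur_min_s <= dur <= dur_max_s):
            continue
        seg = x[a:b]
        upward = int(np.count_nonzero((seg[:-1] <= 0) & (seg[1:] > 0)))
        n_osc = max(upward - 1, 0)
        if n_osc < min_oscillations:
            continue
        spec = morlet_spectrum(broadband, fs, a, b, wavelet_freqs)
        ok, peak_freq = _unimodal_in_band(spec, wavelet_freqs)
        if not ok:
            continue
        events.append(SpindleEvent(
            start_s=ra / fs, end_s=rb / fs, duration_s=dur,
            n_oscillations=n_osc, peak_freq_hz=peak_freq,
            rms_peak=float(env[a:b].max())))
    return events


def psd_grid(grid_max_hz: float = 20.0, grid_step_hz: float = 0.1) -> np.ndarray:
    return np.round(np.arange(0.0, grid_max_hz + grid_step_hz / 2,
                              grid_step_hz), 6)


def welch_psd_window(broadband: np.ndarray, fs: float,
                     window: Tuple[float, float], segment_s: float = 4.0,
                     grid: Optional[np.ndarray] = None) -> np.ndarray:
    """Raw Welch PSD (4-s Hann, 50% overlap) of one time window,
    linearly interpolated to the 0.1 Hz grid."""
    if grid is None:
        grid = psd_grid()
    a, b = window
    seg = broadband[int(round(a * fs)): int(round(b * fs))]
    nper = int(round(segment_s * fs))
    if len(seg) < nper:
        raise ValueError(
            f"window {window} shorter than one Welch segment ({segment_s} s)")
    f, p = welch(seg, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)
    return interp1d(f, p, bounds_error=False, fill_value=0.0)(grid)


def psd_norm_constant(broadband: np.ndarray, fs: float,
                      stim_windows: Sequence[Tuple[float, float]],
                      segment_s: float = 4.0,
                      grid: Optional[np.ndarray] = None) -> float:
    """Subject normalizer: mean over stimulated windows of the mean power
    on the 0-20 Hz grid."""
    if not len(stim_windows):
        raise ValueError("at least one stimulated window is required "
                         "for normalization")
    if grid is None:
        grid = psd_grid()
    return float(np.mean([
        welch_psd_window(broadband, fs, w, segment_s, grid).mean()
        for w in stim_windows]))


def compute_normalized_psd(broadband: np.ndarray, fs: float,
                           windows: Sequence[Tuple[float, float]],
                           stim_windows_for_norm: Sequence[Tuple[float, float]],
                           segment_s: float = 4.0, grid_max_hz: float = 20.0,
                           grid_step_hz: float = 0.1,
                           swa_band=(0.5, 4.0),
                           norm_constant: Optional[float] = None) -> List[SpectralEstimate]:
    """Welch PSD per window, interpolated to the 0.1 Hz grid and normalized.

    The subject-level normalizer is the mean over ``stim_windows_for_norm``
    of the mean power on the 0-20 Hz grid, so after normalization the mean
    total power across those windows is exactly 1.  A precomputed
    ``norm_constant`` may be passed to avoid recomputation.
    """
    grid = psd_grid(grid_max_hz, grid_step_hz)
    swa_idx = (grid >= swa_band[0]) & (grid <= swa_band[1])
    if norm_constant is None:
        norm_constant = psd_norm_constant(broadband, fs, stim_windows_for_norm,
                                          segment_s, grid)
    out = []
    for w in windows:
        p = welch_psd_window(broadband, fs, w, segment_s, grid) / norm_constant
        out.append(SpectralEstimate(freqs=grid, power=p,
                                    swa=float(p[swa_idx].mean()),
                                    norm_constant=norm_constant))
    return out


def classify_stim_dependent_spindles(spindles: Sequence[SpindleEvent],
                                     evoked_so: SlowOscillationEvent,
                                     window_end_s: float) -> bool:
    """True iff at least one spindle initiates in (SO trough, window end]."""
    return any(evoked_so.trough_s < sp.start_s <= window_end_s
               for sp in spindles)
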