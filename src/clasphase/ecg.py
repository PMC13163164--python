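"""ECG processing: R-peak detection, instantaneous heart rate on a 10 Hz
grid, and decomposition into LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz)
components.

The R-peak detector is a squared-derivative energy detector with an
adaptive threshold and a 250 ms refractory period; any detector with beat
timing jitter below ~10 ms would serve.  Instantaneous HR is 60/RR
anchored at each interval's end beat, with |z| > 10 RR outliers excluded
over whole-recording statistics, then cubic-spline interpolated to the
uniform 10 Hz grid.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import find_peaks

from .eeg import zero_phase_bandpass

__all__ = ["RPeakSeries", "HeartRateSeries", "detect_r_peaks",
           "derive_instantaneous_hr", "decompose_hr"]


@dataclass
class RPeakSeries:
    peak_times_s: np.ndarray
    rr_s: np.ndarray
    valid_mask: np.ndarray   # per RR interval: physiologically plausible

    def __post_init__(self):
        if len(self.peak_times_s) > 1 and np.any(np.diff(self.peak_times_s) <= 0):
            raise ValueError("peak times must be strictly increasing")


@dataclass
class HeartRateSeries:
    t_s: np.ndarray          # uniform 10 Hz grid
    hr_bpm: np.ndarray
    lf: Optional[np.ndarray] = None
    hf: Optional[np.ndarray] = None
    edge_s: float = 30.0     # first/last stretch where lf/hf are unreliable

    @property
    def fs(self) -> float:
        return 1.0 / (self.t_s[1] - self.t_s[0])

    def reliable_mask(self) -> np.ndarray:
        return ((self.t_s >= self.t_s[0] + self.edge_s)
                & (self.t_s <= self.t_s[-1] - self.edge_s))


def detect_r_peaks(ecg: np.ndarray, fs: float,
                   refractory_s: float = 0.25) -> RPeakSeries:
    """Detect R-peaks on a band-passed (0.5-35 Hz) ECG trace."""
    x = np.asarray(ecg, dtype=float)
    if len(x) < int(fs):
        return RPeakSeries(np.array([]), np.array([]), np.array([], dtype=bool))
    energy = np.gradient(x) ** 2
    w = max(int(round(0.08 * fs)), 1)
    energy = np.convolve(energy, np.ones(w) / w, mode="same")
    scale = np.percentile(energy, 99)
    if scale <= 0 or x.std() == 0:
        warnings.warn("flat ECG signal: no R-peaks detected")
        return RPeakSeries(np.array([]), np.array([]), np.array([], dtype=bool))
    locs, _ = find_peaks(energy, height=0.2 * scale,
                         distance=max(int(refractory_s * fs), 1))
    # refine each detection to the local ECG maximum (the R wave itself)
    half = int(round(0.04 * fs))
    refined = []
    for i in locs:
        a, b = max(i - half, 0), min(i + half + 1, len(x))
        refined.append(a + int(np.argmax(x[a:b])))
    peaks = np.unique(refined)
    times = peaks / fs
    rr = np.diff(times)
    valid = (rr > 0.25) & (rr < 3.0)
    return RPeakSeries(times, rr, valid)


def derive_instantaneous_hr(rpeaks: RPeakSeries, grid_hz: float = 10.0,
                            rr_z_max: float = 10.0,
                            edge_s: float = 30.0) -> HeartRateSeries:
    """60/RR at interval end beats, outlier-pruned, splined to 10 Hz."""
    if len(rpeaks.peak_times_s) < 11:
        raise ValueError("need at least 10 RR intervals to derive HR")
    rr = rpeaks.rr_s
    keep = rpeaks.valid_mask.copy()
    sd = rr.std()
    if sd > 0:
        keep &= np.abs(rr - rr.mean()) / sd <= rr_z_max
    t_end = rpeaks.peak_times_s[1:][keep]
    hr = 60.0 / rr[keep]
    if len(hr) < 10:
        raise ValueError("fewer than 10 valid beats after outlier exclusion")
    dt = 1.0 / grid_hz
    grid = t_end[0] + dt * np.arange(int(np.floor((t_end[-1] - t_end[0]) / dt)) + 1)
    hr_grid = CubicSpline(t_end, hr, bc_type="natural")(grid)
    return HeartRateSeries(t_s=grid, hr_bpm=hr_grid, edge_s=edge_s)


def decompose_hr(hr: HeartRateSeries, lf_band=(0.04, 0.15),
                 hf_band=(0.15, 0.4), order: int = 4) -> HeartRateSeries:
    """Fill the LF and HF components by zero-phase Butterworth band-passes."""
    if hr.t_s[-1] - hr.t_s[0] < 100.0:
        raise ValueError("need at least 100 s of HR to decompose LF/HF")
    fs = hr.fs
    centered = hr.hr_bpm - hr.hr_bpm.mean()
    return HeartRateSeries(
        t_s=hr.t_s, hr_bpm=hr.hr_bpm,
        lf=zero_phase_bandpass(centered, *lf_band, fs, order),
        hf=zero_phase_bandpass(centered, *hf_band, fs, order),
        edge_s=hr.edge_s)
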