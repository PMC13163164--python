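"""STIM / UNSTIM trial construction.

STIM trials are delivered tones whose ±10 s window lies wholly in
artifact-free, arousal-free N2/N3 sleep and which evoke a slow oscillation
(first SO trough within 2.5 s of onset).  UNSTIM trials are the midpoints
of tone-free intervals of at least 20 s meeting the same criteria and
followed by a spontaneous SO — hypothetical tone onsets that sample the
same sleep without stimulation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .eeg import (SlowOscillationEvent, SpindleEvent,
                  classify_stim_dependent_spindles, psd_grid,
                  welch_psd_window)
from .simulate import EPOCH_S, NREM_DEEP

__all__ = ["ToneTrial", "select_stim_tones", "find_unstim_windows",
           "require_evoked_so", "compute_trial_responses", "n2n3_sample_mask"]


@dataclass
class ToneTrial:
    subject_id: int
    onset_s: float
    is_stim: bool
    window: tuple                      # (onset - guard, onset + guard)
    stage: str
    phases: Optional[tuple] = None     # (phi_so, phi_lf, phi_hf) degrees
    evoked_so: Optional[SlowOscillationEvent] = None
    so_p2p_uv: float = np.nan
    swa_norm: float = np.nan
    spindle: Optional[bool] = None
    hr_p2p_bpm: float = np.nan


def n2n3_sample_mask(hypnogram: Sequence[str], n_samples: int,
                     fs: float) -> np.ndarray:
    """Per-sample boolean mask of N2/N3 sleep."""
    mask = np.zeros(n_samples, dtype=bool)
    for i, stage in enumerate(hypnogram):
        if stage in NREM_DEEP:
            a = int(round(i * EPOCH_S * fs))
            b = int(round((i + 1) * EPOCH_S * fs))
            mask[a:min(b, n_samples)] = True
    return mask


def _window_clean(onset: float, guard_s: float, duration_s: float,
                  hypnogram: Sequence[str], artifact_mask: np.ndarray,
                  fs: float, arousals: np.ndarray) -> bool:
    a, b = onset - guard_s, onset + guard_s
    if a < 0 or b > duration_s:
        return False
    first_ep = int(a // EPOCH_S)
    last_ep = min(int(np.ceil(b / EPOCH_S)), len(hypnogram))
    if any(hypnogram[e] not in NREM_DEEP for e in range(first_ep, last_ep)):
        return False
    ia, ib = int(round(a * fs)), int(round(b * fs))
    if np.any(artifact_mask[ia:ib]):
        return False
    for s, e in arousals:
        if s < b and e > a:
            return False
    return True


def select_stim_tones(tones: Sequence[float], hypnogram: Sequence[str],
                      artifact_mask: np.ndarray, arousals: np.ndarray,
                      fs: float, subject_id: int = 0,
                      guard_s: float = 10.0) -> List[ToneTrial]:
    """Keep tones whose ±guard window is wholly clean N2/N3."""
    duration_s = len(artifact_mask) / fs
    out = []
    for t in tones:
        if _window_clean(t, guard_s, duration_s, hypnogram,
                         artifact_mask, fs, arousals):
            out.append(ToneTrial(
                subject_id=subject_id, onset_s=float(t), is_stim=True,
                window=(t - guard_s, t + guard_s),
                stage=hypnogram[int(t // EPOCH_S)]))
    return out


def find_unstim_windows(tones: Sequence[float], hypnogram: Sequence[str],
                        artifact_mask: np.ndarray, arousals: np.ndarray,
                        fs: float, subject_id: int = 0,
                        min_gap_s: float = 20.0,
                        guard_s: float = 10.0) -> List[ToneTrial]:
    """One hypothetical tone per maximal tone-free interval of >= min_gap_s.

    The midpoint of each qualifying interval is the hypothetical onset; it
    must satisfy the same stage/artifact/arousal window criteria as STIM
    tones.  Analysis windows never extend past the interval's ends because
    the interval is at least 2×guard long.
    """
    duration_s = len(artifact_mask) / fs
    bounds = np.r_[0.0, np.sort(np.asarray(tones, dtype=float)), duration_s]
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a < max(min_gap_s, 2 * guard_s):
            continue
        mid = (a + b) / 2.0
        if _window_clean(mid, guard_s, duration_s, hypnogram,
                         artifact_mask, fs, arousals):
            out.append(ToneTrial(
                subject_id=subject_id, onset_s=float(mid), is_stim=False,
                window=(mid - guard_s, mid + guard_s),
                stage=hypnogram[int(mid // EPOCH_S)]))
    return out


def require_evoked_so(trial: ToneTrial,
                      so_events: Sequence[SlowOscillationEvent],
                      max_latency_s: float = 2.5) -> Optional[ToneTrial]:
    """Attach the first SO whose trough falls in (onset, onset + latency];
    return None (trial rejected) if there is none."""
    best = None
    for ev in so_events:
        if trial.onset_s < ev.trough_s <= trial.onset_s + max_latency_s:
            if best is None or ev.trough_s < best.trough_s:
                best = ev
    if best is None:
        return None
    trial.evoked_so = best
    return trial


def compute_trial_responses(trial: ToneTrial, broadband: np.ndarray, fs: float,
                            spindles: Sequence[SpindleEvent],
                            norm_constant: float,
                            hr_t0: Optional[float] = None,
                            hr_bpm: Optional[np.ndarray] = None,
                            hr_fs: float = 10.0,
                            swa_window_s: float = 8.0,
                            hr_window_s: float = 10.0,
                            swa_band=(0.5, 4.0)) -> ToneTrial:
    """Fill the response metrics of a retained trial.

    so_p2p is the evoked SO's peak-to-peak amplitude; swa the normalized
    slow-wave power over [onset, onset + 8 s] (the subject-level
    ``norm_constant`` comes from :func:`clasphase.eeg.psd_norm_constant`);
    the spindle flag marks a spindle initiating after the evoked SO trough;
    hr_p2p the max - min of instantaneous HR over [onset, onset + 10 s]
    (NaN without HR coverage).
    """
    if trial.evoked_so is None:
        raise ValueError("trial must have an evoked SO attached")
    trial.so_p2p_uv = trial.evoked_so.p2p_uv

    grid = psd_grid()
    window = (trial.onset_s, trial.onset_s + swa_window_s)
    p = welch_psd_window(broadband, fs, window, grid=grid) / norm_constant
    swa_idx = (grid >= swa_band[0]) & (grid <= swa_band[1])
    trial.swa_norm = float(p[swa_idx].mean())

    trial.spindle = classify_stim_dependent_spindles(
        spindles, trial.evoked_so, trial.onset_s + hr_window_s)

    if hr_bpm is not None and hr_t0 is not None:
        a = int(round((trial.onset_s - hr_t0) * hr_fs))
        b = int(round((trial.onset_s + hr_window_s - hr_t0) * hr_fs))
        if 0 <= a < b <= len(hr_bpm):
            seg = hr_bpm[a:b]
            trial.hr_p2p_bpm = float(seg.max() - seg.min())
    return trial
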