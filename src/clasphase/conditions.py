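"""Multidimensional upstate/downstate phase-locking comparison.

Tones are grouped by the binary states (U: phase in [0°, 180°); D: phase
in [-180°, 0°)) of EEG SO, HR-LF, and HR-HF at onset into the eight
analyzed conditions ('---' = open-loop through 'UUD' = triple locking).
For each condition, tone-locked ERPs, spectra, per-trial SO amplitude and
SWA are aggregated subject-first, and phase-locking strategies are
compared with Shapiro–Wilk-gated paired t / Wilcoxon signed-rank tests.
"""
from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phase import CONDITION_LABELS, condition_spec

__all__ = [
    "condition_flags", "subject_condition_metrics", "unstim_swa_reference",
    "strategy_effect_table", "compare_strategies", "tone_locked_average",
    "erp_peak_to_peak", "condition_erps", "condition_spectra",
]


def condition_flags(trials: pd.DataFrame,
                    labels: Sequence[str] = CONDITION_LABELS) -> pd.DataFrame:
    """Boolean matrix (n_trials × labels) of condition membership."""
    phase_cols = ("phi_so", "phi_lf", "phi_hf")
    states = np.stack(
        [np.where(trials[c].to_numpy() >= 0, "U", "D") for c in phase_cols],
        axis=1)
    known = trials[list(phase_cols)].notna().to_numpy()
    out = {}
    for lab in labels:
        spec = condition_spec(lab)
        m = np.ones(len(trials), dtype=bool)
        for k, req in enumerate(spec):
            if req != "-":
                # a constrained slot needs a known phase in the right state
                m &= known[:, k] & (states[:, k] == req)
        out[lab] = m
    return pd.DataFrame(out, index=trials.index)


def subject_condition_metrics(trials: pd.DataFrame,
                              labels: Sequence[str] = CONDITION_LABELS,
                              min_trials: int = 5) -> pd.DataFrame:
    """Per subject × condition × (STIM/UNSTIM): trial count, mean SO
    peak-to-peak amplitude, mean normalized SWA, spindle likelihood."""
    flags = condition_flags(trials, labels)
    rows = []
    for subj, sub in trials.groupby("subject_id"):
        fl = flags.loc[sub.index]
        for lab in labels:
            for is_stim in (True, False):
                sel = sub[fl[lab] & (sub["is_stim"] == is_stim)]
                n = len(sel)
                if n < min_trials:
                    continue
                rows.append(dict(
                    subject_id=subj, condition=lab, is_stim=is_stim,
                    n_trials=n,
                    so_amp_uv=float(sel["so_p2p_uv"].mean()),
                    swa_norm=float(sel["swa_norm"].mean()),
                    spindle_lik=float(sel["spindle"].mean())
                    if sel["spindle"].notna().any() else np.nan))
    return pd.DataFrame(rows)


def unstim_swa_reference(metrics: pd.DataFrame) -> float:
    """Grand mean over subjects of unstimulated open-loop ('---') SWA.

    SWA percentages are expressed relative to this value, so the
    unstimulated open-loop condition reads 100 by definition.
    """
    ref = metrics[(metrics["condition"] == "---") & (~metrics["is_stim"])]
    if ref.empty:
        raise ValueError("no unstimulated open-loop rows to anchor SWA%")
    return float(ref["swa_norm"].mean())


def strategy_effect_table(metrics: pd.DataFrame,
                          labels: Sequence[str] = CONDITION_LABELS) -> pd.DataFrame:
    """Condition × {stim/unstim SO amplitude, SWA%} grid plus
    enhancement-vs-open-loop deltas (subject-paired means)."""
    ref = unstim_swa_reference(metrics)
    piv = metrics.pivot_table(index=["subject_id", "condition"],
                              columns="is_stim",
                              values=["so_amp_uv", "swa_norm", "n_trials"])
    rows = []
    open_stim = metrics[(metrics["condition"] == "---") & metrics["is_stim"]] \
        .set_index("subject_id")
    for lab in labels:
        sel = metrics[metrics["condition"] == lab]
        stim = sel[sel["is_stim"]]
        unstim = sel[~sel["is_stim"]]
        incomplete = stim.empty or unstim.empty
        # subject-paired enhancement relative to open-loop stimulation
        joined = stim.set_index("subject_id").join(
            open_stim, rsuffix="_open", how="inner")
        rows.append(dict(
            condition=lab,
            n_subjects_stim=len(stim), n_subjects_unstim=len(unstim),
            mean_n_stim=float(stim["n_trials"].mean()) if len(stim) else np.nan,
            mean_n_unstim=float(unstim["n_trials"].mean()) if len(unstim) else np.nan,
            stim_so_amp_uv=float(stim["so_amp_uv"].mean()) if len(stim) else np.nan,
            stim_swa_pct=100.0 * float(stim["swa_norm"].mean()) / ref
            if len(stim) else np.nan,
            unstim_so_amp_uv=float(unstim["so_amp_uv"].mean()) if len(unstim) else np.nan,
            unstim_swa_pct=100.0 * float(unstim["swa_norm"].mean()) / ref
            if len(unstim) else np.nan,
            so_enhancement_uv=float(
                (joined["so_amp_uv"] - joined["so_amp_uv_open"]).mean())
            if len(joined) else np.nan,
            swa_enhancement_pct=100.0 * float(
                (joined["swa_norm"] - joined["swa_norm_open"]).mean()) / ref
            if len(joined) else np.nan,
            incomplete=incomplete))
    return pd.DataFrame(rows)


def compare_strategies(metrics: pd.DataFrame,
                       pairs: Sequence[Tuple[str, str]],
                       value: str = "so_amp_uv", stim: bool = True,
                       alpha: float = 0.05,
                       min_subjects: int = 5) -> pd.DataFrame:
    """Shapiro–Wilk-gated paired tests between phase-locking strategies.

    Per pair, subjects present in both conditions contribute a difference;
    a paired t-test is used when the differences pass Shapiro–Wilk
    normality at ``alpha``, otherwise the Wilcoxon signed-rank test.
    """
    wide = metrics[metrics["is_stim"] == stim].pivot_table(
        index="subject_id", columns="condition", values=value)
    rows = []
    for a, b in pairs:
        if a not in wide.columns or b not in wide.columns:
            rows.append(dict(cond_a=a, cond_b=b, n=0, test="untested",
                             shapiro_p=np.nan, statistic=np.nan, p_value=np.nan))
            continue
        d = (wide[a] - wide[b]).dropna()
        if len(d) < min_subjects:
            rows.append(dict(cond_a=a, cond_b=b, n=len(d), test="untested",
                             shapiro_p=np.nan, statistic=np.nan, p_value=np.nan))
            continue
        if np.allclose(d, 0):
            rows.append(dict(cond_a=a, cond_b=b, n=len(d), test="degenerate",
                             shapiro_p=np.nan, statistic=0.0, p_value=1.0))
            continue
        sw_p = float(sps.shapiro(d).pvalue)
        if sw_p >= alpha:
            stat, p = sps.ttest_rel(wide.loc[d.index, a], wide.loc[d.index, b])
            test = "paired_t"
        else:
            stat, p = sps.wilcoxon(d)
            test = "wilcoxon"
        rows.append(dict(cond_a=a, cond_b=b, n=len(d), test=test,
                         shapiro_p=sw_p, statistic=float(stat),
                         p_value=float(p)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ERPs and spectra
# ---------------------------------------------------------------------------

def tone_locked_average(eeg: np.ndarray, fs: float, onsets: Sequence[float],
                        window: Tuple[float, float] = (-2.0, 10.0)
                        ) -> Optional[np.ndarray]:
    """Average EEG segments time-locked to the given onsets (one subject)."""
    n0 = int(round(window[0] * fs))
    n1 = int(round(window[1] * fs))
    segs = []
    for t in onsets:
        i = int(round(t * fs))
        if i + n0 >= 0 and i + n1 <= len(eeg):
            segs.append(eeg[i + n0: i + n1])
    if not segs:
        return None
    return np.mean(segs, axis=0)


def erp_peak_to_peak(erp: np.ndarray, fs: float,
                     window: Tuple[float, float] = (-2.0, 10.0),
                     search: Tuple[float, float] = (0.0, 3.0)) -> float:
    """Max − min of the ERP within the post-onset extrema search span."""
    a = int(round((search[0] - window[0]) * fs))
    b = int(round((search[1] - window[0]) * fs))
    seg = erp[a:b]
    return float(seg.max() - seg.min())


def condition_erps(trials: pd.DataFrame, eeg_by_subject: Dict[int, np.ndarray],
                   fs: float, labels: Sequence[str] = CONDITION_LABELS,
                   window: Tuple[float, float] = (-2.0, 10.0),
                   search: Tuple[float, float] = (0.0, 3.0),
                   min_trials: int = 5) -> pd.DataFrame:
    """Group ERPs and difference waveforms per condition.

    Subject ERPs are averaged first, then across subjects; the returned
    frame has one row per condition with stim/unstim/diff ERP arrays and
    their peak-to-peak amplitudes in the extrema window.
    """
    flags = condition_flags(trials, labels)
    rows = []
    for lab in labels:
        stim_erps, unstim_erps = [], []
        for subj, sub in trials.groupby("subject_id"):
            if subj not in eeg_by_subject:
                continue
            fl = flags.loc[sub.index, lab]
            for is_stim, bucket in ((True, stim_erps), (False, unstim_erps)):
                onsets = sub.loc[fl & (sub["is_stim"] == is_stim), "onset_s"]
                if len(onsets) < min_trials:
                    continue
                erp = tone_locked_average(eeg_by_subject[subj], fs,
                                          onsets.to_numpy(), window)
                if erp is not None:
                    bucket.append(erp)
        stim = np.mean(stim_erps, axis=0) if stim_erps else None
        unstim = np.mean(unstim_erps, axis=0) if unstim_erps else None
        diff = stim - unstim if stim is not None and unstim is not None else None
        rows.append(dict(
            condition=lab,
            n_subjects_stim=len(stim_erps), n_subjects_unstim=len(unstim_erps),
            stim_erp=stim, unstim_erp=unstim, diff_erp=diff,
            stim_p2p_uv=erp_peak_to_peak(stim, fs, window, search)
            if stim is not None else np.nan,
            unstim_p2p_uv=erp_peak_to_peak(unstim, fs, window, search)
            if unstim is not None else np.nan,
            diff_p2p_uv=erp_peak_to_peak(diff, fs, window, search)
            if diff is not None else np.nan))
    return pd.DataFrame(rows)


def condition_spectra(trials: pd.DataFrame, psd_matrix: np.ndarray,
                      freqs: np.ndarray,
                      labels: Sequence[str] = CONDITION_LABELS,
                      min_trials: int = 5) -> Dict[str, pd.DataFrame]:
    """Condition-average normalized PSDs (trials → subject → group) and
    STIM − UNSTIM difference spectra.

    ``psd_matrix`` holds one normalized PSD row per trial, aligned with
    ``trials``.
    """
    flags = condition_flags(trials, labels)
    out = {}
    for lab in labels:
        stim_curves, unstim_curves = [], []
        for subj, sub in trials.groupby("subject_id"):
            fl = flags.loc[sub.index, lab].to_numpy()
            pos = trials.index.get_indexer(sub.index)
            for is_stim, bucket in ((True, stim_curves), (False, unstim_curves)):
                sel = fl & (sub["is_stim"] == is_stim).to_numpy()
                if sel.sum() < min_trials:
                    continue
                bucket.append(psd_matrix[pos[sel]].mean(axis=0))
        stim = np.mean(stim_curves, axis=0) if stim_curves else np.full(len(freqs), np.nan)
        unstim = np.mean(unstim_curves, axis=0) if unstim_curves else np.full(len(freqs), np.nan)
        out[lab] = pd.DataFrame({"freq_hz": freqs, "stim": stim,
                                 "unstim": unstim, "diff": stim - unstim})
    return out
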