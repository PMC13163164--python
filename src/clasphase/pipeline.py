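"""End-to-end orchestration: simulate (or load) → preprocess → phases →
trials → continuous phase analysis → multidimensional analysis → report.

Every stage writes flat CSV artifacts plus one JSON manifest per run; the
logged funnel (tones in → stage/artifact pass → SO-evoked) mirrors the
trial-selection chain and never increases along it.
"""
from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import conditions as cond
from . import stats as st
from .config import AnalysisParams, RunConfig, SimConfig
from .ecg import decompose_hr, derive_instantaneous_hr, detect_r_peaks
from .eeg import (detect_slow_oscillations, detect_spindles, filter_eeg,
                  psd_grid, psd_norm_constant, welch_psd_window,
                  zero_phase_bandpass)
from .phase import PhaseBinGrid, instantaneous_phase, phase_at
from .simulate import EPOCH_S, Recording, generate_recording
from .trials import (compute_trial_responses, find_unstim_windows,
                     n2n3_sample_mask, require_evoked_so, select_stim_tones)

STAGES = ("simulate", "preprocess", "phases", "trials",
          "continuous", "multidim", "report")

__all__ = ["SubjectData", "CohortData", "process_subject", "run_cohort",
           "run_pipeline", "STAGES"]


@dataclass
class SubjectData:
    subject_id: int
    trials: pd.DataFrame
    psd_rows: np.ndarray                 # per-trial normalized PSD curves
    broadband: np.ndarray                # float32, for ERP averaging
    fs: float
    funnel: Dict[str, int]
    n_so_events: int
    n_spindles: int


@dataclass
class CohortData:
    trials: pd.DataFrame
    psd_matrix: np.ndarray
    freqs: np.ndarray
    eeg_by_subject: Dict[int, np.ndarray]
    fs_eeg: float
    funnel: pd.DataFrame


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage


def process_subject(rec: Recording, params: AnalysisParams,
                    use_ecg: bool = True) -> Optional[SubjectData]:
    """Run one subject from raw signals to a response-annotated trial table.

    Returns None when no STIM trial survives selection (the subject then
    contributes nothing downstream).
    """
    fs = rec.fs_eeg
    filt = filter_eeg(rec.eeg, fs, params.broadband, params.so_band,
                      params.spindle_band, params.filter_order,
                      artifact_kwargs=dict(segment_s=params.artifact_segment_s,
                                           amp_limit_uv=params.artifact_amp_uv,
                                           sd_z=params.artifact_sd_z))
    n2n3 = n2n3_sample_mask(rec.hypnogram, len(rec.eeg), fs)

    so_events = detect_slow_oscillations(
        filt.so_band, fs, filt.artifact_mask, params.so_trough_max_uv,
        params.so_p2p_min_uv, params.so_dur_min_s, params.so_dur_max_s)
    if params.so_min_p2p_filter_uv is not None:
        so_events = [e for e in so_events
                     if e.p2p_uv > params.so_min_p2p_filter_uv]
    spindles = detect_spindles(
        filt.spindle_band, filt.broadband, fs, n2n3, filt.artifact_mask,
        params.spindle_percentile, params.spindle_rms_window_s,
        params.spindle_dur_min_s, params.spindle_dur_max_s,
        params.spindle_min_oscillations)

    # --- heart rate ------------------------------------------------------
    hr = None
    if use_ecg and rec.ecg is not None and len(rec.ecg):
        try:
            ecg_f = zero_phase_bandpass(rec.ecg, *params.ecg_band, rec.fs_ecg,
                                        params.filter_order)
            rpeaks = detect_r_peaks(ecg_f, rec.fs_ecg)
            hr = derive_instantaneous_hr(rpeaks, params.hr_grid_hz,
                                         params.rr_z_max, params.hr_edge_s)
            hr = decompose_hr(hr, params.lf_band, params.hf_band,
                              params.filter_order)
        except ValueError as e:
            warnings.warn(f"subject {rec.subject_id}: HR derivation failed "
                          f"({e}); HR-dependent outputs skipped")
            hr = None

    # --- instantaneous phases -------------------------------------------
    phi_so_series = instantaneous_phase(filt.so_band, fs,
                                        valid_mask=~filt.artifact_mask)
    if hr is not None:
        rel = hr.reliable_mask()
        phi_lf_series = instantaneous_phase(hr.lf, hr.fs)
        phi_hf_series = instantaneous_phase(hr.hf, hr.fs)
        phi_lf_series[~rel] = np.nan
        phi_hf_series[~rel] = np.nan

    # --- trial selection funnel -----------------------------------------
    n_tones = len(rec.tones)
    stage_pass = [t for t in rec.tones
                  if rec.hypnogram[int(t // EPOCH_S)] in ("N2", "N3")]
    stim = select_stim_tones(rec.tones, rec.hypnogram, filt.artifact_mask,
                             rec.arousals, fs, rec.subject_id, params.guard_s)
    unstim = find_unstim_windows(rec.tones, rec.hypnogram, filt.artifact_mask,
                                 rec.arousals, fs, rec.subject_id,
                                 params.unstim_min_gap_s, params.guard_s)
    n_clean = len(stim)
    stim = [t for t in (require_evoked_so(tr, so_events,
                                          params.evoked_so_max_latency_s)
                        for tr in stim) if t is not None]
    unstim = [t for t in (require_evoked_so(tr, so_events,
                                            params.evoked_so_max_latency_s)
                          for tr in unstim) if t is not None]
    funnel = dict(tones_scheduled=n_tones, tones_n2n3=len(stage_pass),
                  tones_clean_window=n_clean, stim_trials=len(stim),
                  unstim_trials=len(unstim))
    if not stim:
        return None

    # --- responses -------------------------------------------------------
    grid = psd_grid(params.psd_grid_max_hz, params.psd_grid_step_hz)
    stim_windows = [(t.onset_s, t.onset_s + params.swa_window_s) for t in stim]
    norm_c = psd_norm_constant(filt.broadband, fs, stim_windows,
                               params.welch_segment_s, grid)
    swa_idx = (grid >= params.swa_band[0]) & (grid <= params.swa_band[1])

    rows, psd_rows = [], []
    for tr in stim + unstim:
        compute_trial_responses(
            tr, filt.broadband, fs, spindles, norm_c,
            hr_t0=hr.t_s[0] if hr is not None else None,
            hr_bpm=hr.hr_bpm if hr is not None else None,
            hr_fs=hr.fs if hr is not None else 10.0,
            swa_window_s=params.swa_window_s,
            hr_window_s=params.hr_response_window_s,
            swa_band=params.swa_band)
        phi_so = phase_at(phi_so_series, 0.0, fs, [tr.onset_s])[0]
        if hr is not None:
            phi_lf = phase_at(phi_lf_series, hr.t_s[0], hr.fs, [tr.onset_s])[0]
            phi_hf = phase_at(phi_hf_series, hr.t_s[0], hr.fs, [tr.onset_s])[0]
        else:
            phi_lf = phi_hf = np.nan
        tr.phases = (phi_so, phi_lf, phi_hf)
        rows.append(dict(subject_id=rec.subject_id, onset_s=tr.onset_s,
                         is_stim=tr.is_stim, stage=tr.stage,
                         phi_so=phi_so, phi_lf=phi_lf, phi_hf=phi_hf,
                         so_p2p_uv=tr.so_p2p_uv, swa_norm=tr.swa_norm,
                         spindle=tr.spindle, hr_p2p_bpm=tr.hr_p2p_bpm))
        psd_rows.append(welch_psd_window(filt.broadband, fs,
                                         (tr.onset_s,
                                          tr.onset_s + params.swa_window_s),
                                         params.welch_segment_s, grid) / norm_c)
    return SubjectData(
        subject_id=rec.subject_id, trials=pd.DataFrame(rows),
        psd_rows=np.asarray(psd_rows, dtype=np.float32),
        broadband=filt.broadband.astype(np.float32), fs=fs, funnel=funnel,
        n_so_events=len(so_events), n_spindles=len(spindles))


def run_cohort(sim: SimConfig, params: AnalysisParams,
               use_ecg: bool = True,
               keep_eeg: bool = True) -> CohortData:
    """Simulate and process every subject; concatenate trial tables."""
    all_trials, psd_blocks, eeg_by_subject, funnel_rows = [], [], {}, []
    for i in range(sim.n_subjects):
        rec, _truth = generate_recording(sim, i)
        sd = process_subject(rec, params, use_ecg)
        if sd is None:
            continue
        all_trials.append(sd.trials)
        psd_blocks.append(sd.psd_rows)
        if keep_eeg:
            eeg_by_subject[sd.subject_id] = sd.broadband
        funnel_rows.append(dict(subject_id=sd.subject_id, **sd.funnel,
                                n_so_events=sd.n_so_events,
                                n_spindles=sd.n_spindles))
    if not all_trials:
        raise RuntimeError("no subject produced any retained STIM trial")
    trials = pd.concat(all_trials, ignore_index=True)
    return CohortData(trials=trials,
                      psd_matrix=np.concatenate(psd_blocks, axis=0),
                      freqs=psd_grid(params.psd_grid_max_hz,
                                     params.psd_grid_step_hz),
                      eeg_by_subject=eeg_by_subject, fs_eeg=sim.fs_eeg,
                      funnel=pd.DataFrame(funnel_rows))


STRATEGY_PAIRS = [
    ("-U-", "-UD"), ("--D", "-UD"), ("-U-", "--D"),
    ("UU-", "U--"), ("U-D", "U--"),
    ("UUD", "UU-"), ("UUD", "U-D"), ("UUD", "U--"),
]


def run_pipeline(config: RunConfig, through_stage: str = "report") -> dict:
    """Execute the pipeline and write artifacts under ``config.outdir``.

    Stops after ``through_stage`` (one of ``STAGES``).  Returns a manifest
    dictionary (also written as JSON) with paths, counts, and versions.
    """
    if through_stage not in STAGES:
        raise ValueError(f"unknown stage {through_stage!r}; pick from {STAGES}")
    last = STAGES.index(through_stage)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    config.sim.seed = int(config.seed)
    config.to_yaml(outdir / "config.yaml")
    manifest: dict = {
        "seed": int(config.seed),
        "config_sha256": hashlib.sha256(
            (outdir / "config.yaml").read_bytes()).hexdigest(),
        "versions": _versions(),
        "stages_run": [],
        "artifacts": {},
    }

    def record(stage, **arts):
        manifest["stages_run"].append(stage)
        manifest["artifacts"].update({k: str(v) for k, v in arts.items()})

    try:
        cohort = run_cohort(config.sim, config.params, config.use_ecg,
                            keep_eeg=last >= STAGES.index("multidim"))
    except Exception as e:  # pragma: no cover - stage-named failure contract
        raise StageError("simulate", e) from e
    record("simulate")
    record("preprocess")
    record("phases")

    trials_path = outdir / "trials.csv"
    funnel_path = outdir / "funnel.csv"
    cohort.trials.to_csv(trials_path, index=False, float_format="%.6f")
    cohort.funnel.to_csv(funnel_path, index=False)
    record("trials", trials=trials_path, funnel=funnel_path)
    manifest["n_stim_trials"] = int(cohort.trials["is_stim"].sum())
    manifest["n_unstim_trials"] = int((~cohort.trials["is_stim"]).sum())

    if last >= STAGES.index("continuous"):
        try:
            tables = st.continuous_phase_analysis(
                cohort.trials, grid=PhaseBinGrid(config.params.bin_width_deg,
                                                 config.params.bin_step_deg),
                n_mc=config.params.n_mc, min_trials=config.params.min_trials,
                min_subjects=config.params.min_subjects,
                alpha=config.params.alpha, seed=config.seed,
                include_hr=config.use_ecg)
        except Exception as e:
            raise StageError("continuous", e) from e
        cdir = outdir / "continuous"
        cdir.mkdir(exist_ok=True)
        for name, table in tables.items():
            p = cdir / f"{name}.csv"
            table.to_csv(p, index=False, float_format="%.6g")
            record("continuous", **{f"continuous/{name}": p})

    if last >= STAGES.index("multidim"):
        try:
            metrics = cond.subject_condition_metrics(
                cohort.trials, min_trials=config.params.min_trials)
            table2 = cond.strategy_effect_table(metrics)
            comps = cond.compare_strategies(metrics, STRATEGY_PAIRS,
                                            alpha=config.params.alpha)
            erps = cond.condition_erps(
                cohort.trials, cohort.eeg_by_subject, cohort.fs_eeg,
                window=config.params.erp_window_s,
                search=config.params.erp_extrema_window_s,
                min_trials=config.params.min_trials)
        except Exception as e:
            raise StageError("multidim", e) from e
        mdir = outdir / "multidim"
        mdir.mkdir(exist_ok=True)
        metrics.to_csv(mdir / "condition_metrics.csv", index=False,
                       float_format="%.6f")
        table2.to_csv(mdir / "strategy_effects.csv", index=False,
                      float_format="%.6f")
        comps.to_csv(mdir / "strategy_comparisons.csv", index=False,
                     float_format="%.6g")
        erp_out = erps.drop(columns=["stim_erp", "unstim_erp", "diff_erp"])
        erp_out.to_csv(mdir / "condition_erp_amplitudes.csv", index=False,
                       float_format="%.6f")
        _write_erp_curves(erps, cohort.fs_eeg, config.params.erp_window_s,
                          mdir / "condition_erp_curves.csv")
        spectra = cond.condition_spectra(cohort.trials, cohort.psd_matrix,
                                         cohort.freqs,
                                         min_trials=config.params.min_trials)
        spec_rows = []
        for lab, df in spectra.items():
            df = df.copy()
            df.insert(0, "condition", lab)
            spec_rows.append(df)
        pd.concat(spec_rows, ignore_index=True).to_csv(
            mdir / "condition_spectra.csv", index=False, float_format="%.6g")
        record("multidim", condition_metrics=mdir / "condition_metrics.csv",
               strategy_effects=mdir / "strategy_effects.csv",
               strategy_comparisons=mdir / "strategy_comparisons.csv",
               erp_amplitudes=mdir / "condition_erp_amplitudes.csv",
               erp_curves=mdir / "condition_erp_curves.csv")

    if last >= STAGES.index("report"):
        record("report")
    manifest["funnel_totals"] = {
        k: int(cohort.funnel[k].sum())
        for k in ("tones_scheduled", "tones_n2n3", "tones_clean_window",
                  "stim_trials", "unstim_trials")}
    manifest["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_erp_curves(erps: pd.DataFrame, fs: float, window,
                      path: Path) -> None:
    n0 = int(round(window[0] * fs))
    n1 = int(round(window[1] * fs))
    t = np.arange(n0, n1) / fs
    cols = {"time_s": t}
    for _, row in erps.iterrows():
        for which in ("stim", "unstim", "diff"):
            arr = row[f"{which}_erp"]
            if arr is not None:
                cols[f"{row['condition']}_{which}"] = arr
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.4f")


def _versions() -> dict:
    import scipy
    import statsmodels
    return {"numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__, "statsmodels": statsmodels.__version__}
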