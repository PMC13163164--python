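#!/usr/bin/env python
"""Detect slow oscillations and spindles on the demo cohort and score them
against the generator's ground truth.

Reads the EDF/CSV cohort written by 01_simulate_cohort.py (regenerating it
in memory if absent), runs the EEG band decomposition and both detectors,
writes event tables under results/events/, and reports recovery rates.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from clasphase import AnalysisParams, SimConfig, generate_recording
from clasphase.eeg import detect_slow_oscillations, detect_spindles, filter_eeg
from clasphase.trials import n2n3_sample_mask

OUT = Path("results/events")

if __name__ == "__main__":
    cfg = SimConfig(n_subjects=3, duration_s=1800.0, seed=42)
    params = AnalysisParams()
    OUT.mkdir(parents=True, exist_ok=True)
    for i in range(cfg.n_subjects):
        rec, truth = generate_recording(cfg, i)
        filt = filter_eeg(rec.eeg, rec.fs_eeg)
        n2n3 = n2n3_sample_mask(rec.hypnogram, len(rec.eeg), rec.fs_eeg)
        sos = detect_slow_oscillations(filt.so_band, rec.fs_eeg,
                                       filt.artifact_mask)
        spindles = detect_spindles(filt.spindle_band, filt.broadband,
                                   rec.fs_eeg, n2n3, filt.artifact_mask)
        pd.DataFrame([vars(e) for e in sos]).to_csv(
            OUT / f"subject_{i:03d}_so_events.csv", index=False)
        pd.DataFrame([vars(e) for e in spindles]).to_csv(
            OUT / f"subject_{i:03d}_spindles.csv", index=False)

        det_troughs = np.array([e.trough_s for e in sos])
        inj = truth.so_events["trough_s"].to_numpy()
        so_recovery = np.mean([np.any(np.abs(det_troughs - t) < 0.25)
                               for t in inj]) if len(inj) else float("nan")
        det_sp = np.array([e.start_s for e in spindles])
        inj_sp = truth.spindles["start_s"].to_numpy()
        sp_recovery = np.mean([np.any(np.abs(det_sp - t) < 0.4)
                               for t in inj_sp]) if len(inj_sp) else float("nan")
        print(f"subject {i}: {len(sos)} SOs detected "
              f"({100 * so_recovery:.0f}% of injected recovered), "
              f"{len(spindles)} spindles "
              f"({100 * sp_recovery:.0f}% of injected recovered)")
    print(f"event tables in {OUT}/")
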