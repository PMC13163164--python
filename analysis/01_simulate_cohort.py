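#!/usr/bin/env python
"""Generate a small demonstration cohort and persist it as EDF + CSV.

Writes per-subject EDF signals (EEG μV, ECG mV), hypnogram/tone/arousal
CSVs and the ground-truth manifest under results/cohort/, and prints what
was injected per subject.
"""
from pathlib import Path

from clasphase import SimConfig, generate_recording
from clasphase.io import write_ground_truth, write_recording

OUT = Path("results/cohort")

if __name__ == "__main__":
    cfg = SimConfig(n_subjects=3, duration_s=1800.0, seed=42)
    OUT.mkdir(parents=True, exist_ok=True)
    for i in range(cfg.n_subjects):
        rec, truth = generate_recording(cfg, i)
        write_recording(rec, OUT)
        write_ground_truth(truth, OUT / f"subject_{i:03d}_truth.json")
        deep = sum(s in ("N2", "N3") for s in rec.hypnogram) / len(rec.hypnogram)
        print(f"subject {i}: {len(rec.tones)} tones, "
              f"{len(truth.so_events)} spontaneous SOs, "
              f"{len(truth.spindles)} spindles, "
              f"{100 * deep:.0f}% N2/N3, "
              f"mean evoked amplitude "
              f"{truth.tones.evoked_amp_uv.mean():.1f} μV")
    print(f"wrote {cfg.n_subjects} subjects to {OUT}/")
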