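"""File interchange: EDF signals, CSV annotations, JSON/YAML manifests.

EDF reading goes through MNE.  No installed library exposes EDF *writing*,
so a compact standard-conformant writer (16-bit, one-second data records)
is provided here and round-tripped against MNE's reader in the tests.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

from .simulate import GroundTruth, Recording

__all__ = ["write_edf", "read_edf_signals", "write_recording",
           "read_recording", "write_ground_truth"]


def _field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path, signals: Sequence[np.ndarray], fs_list: Sequence[float],
              labels: Sequence[str], units: Sequence[str]) -> None:
    """Write channels with integer sampling rates to an EDF file.

    Signals are scaled to the full 16-bit digital range per channel; the
    trailing partial second, if any, is zero-padded.
    """
    n_sig = len(signals)
    fs_int = [int(round(f)) for f in fs_list]
    if any(abs(f - fi) > 1e-9 for f, fi in zip(fs_list, fs_int)):
        raise ValueError("EDF writer requires integer sampling rates")
    n_records = max(int(np.ceil(len(x) / f)) for x, f in zip(signals, fs_int))

    header = b"".join([
        _field(0, 8), _field("X X X X", 80), _field("Startdate X X X X", 80),
        _field("01.01.00", 8), _field("00.00.00", 8),
        _field(256 * (1 + n_sig), 8), _field("", 44),
        _field(n_records, 8), _field(1, 8), _field(n_sig, 4),
    ])
    phys_min, phys_max, scaled = [], [], []
    for x in signals:
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            lo, hi = lo - 1.0, lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((x - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(dig.astype("<i2"))
    for vals, width in [
        (labels, 16), (["" for _ in signals], 80), (units, 8),
        ([f"{v:.6g}" for v in phys_min], 8),
        ([f"{v:.6g}" for v in phys_max], 8),
        ([-32768] * n_sig, 8), ([32767] * n_sig, 8),
        (["" for _ in signals], 80), (fs_int, 8),
        (["" for _ in signals], 32),
    ]:
        header += b"".join(_field(v, width) for v in vals)

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for x, f in zip(scaled, fs_int):
                chunk = x[r * f:(r + 1) * f]
                if len(chunk) < f:
                    chunk = np.r_[chunk, np.zeros(f - len(chunk), dtype="<i2")]
                fh.write(chunk.tobytes())


def read_edf_signals(path) -> Tuple[List[np.ndarray], List[float], List[str]]:
    """Read EDF channels via MNE; returns (signals, sampling rates, labels).

    MNE resamples all channels to a common rate internally; signals come
    back in the file's physical units.
    """
    import mne
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    sigs, labels = [], []
    for name in raw.ch_names:
        data = raw.get_data(picks=[name])[0]
        orig_unit = raw._orig_units.get(name, "") if hasattr(raw, "_orig_units") else ""
        if orig_unit in ("µV", "uV"):
            data = data * 1e6
        elif orig_unit == "mV":
            data = data * 1e3
        elif orig_unit == "V":
            pass
        sigs.append(data)
        labels.append(name)
    return sigs, [fs] * len(sigs), labels


def write_recording(rec: Recording, outdir) -> dict:
    """Persist one subject: EDF signals + CSV annotations."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = rec.subject_id
    paths = {
        "edf": outdir / f"subject_{sid:03d}.edf",
        "hypnogram": outdir / f"subject_{sid:03d}_hypnogram.csv",
        "tones": outdir / f"subject_{sid:03d}_tones.csv",
        "arousals": outdir / f"subject_{sid:03d}_arousals.csv",
    }
    write_edf(paths["edf"], [rec.eeg, rec.ecg], [rec.fs_eeg, rec.fs_ecg],
              ["EEG F3-M2", "ECG"], ["uV", "mV"])
    pd.DataFrame({"epoch_index": range(len(rec.hypnogram)),
                  "stage": rec.hypnogram}).to_csv(paths["hypnogram"], index=False)
    pd.DataFrame({"onset_s": rec.tones}).to_csv(paths["tones"], index=False)
    pd.DataFrame(rec.arousals, columns=["start_s", "end_s"]).to_csv(
        paths["arousals"], index=False)
    return {k: str(v) for k, v in paths.items()}


def read_recording(outdir, subject_id: int) -> Recording:
    """Load a subject written by :func:`write_recording`."""
    outdir = Path(outdir)
    sid = subject_id
    sigs, fss, labels = read_edf_signals(outdir / f"subject_{sid:03d}.edf")
    hyp = pd.read_csv(outdir / f"subject_{sid:03d}_hypnogram.csv")
    tones = pd.read_csv(outdir / f"subject_{sid:03d}_tones.csv")
    arousals = pd.read_csv(outdir / f"subject_{sid:03d}_arousals.csv")
    return Recording(
        subject_id=sid, fs_eeg=fss[0], fs_ecg=fss[1],
        eeg=sigs[0], ecg=sigs[1],
        hypnogram=list(hyp["stage"]),
        arousals=arousals.to_numpy(dtype=float).reshape(-1, 2),
        tones=tones["onset_s"].to_numpy(dtype=float))


def write_ground_truth(truth: GroundTruth, path) -> None:
    """Ground-truth manifest as JSON (tables embedded as records)."""
    d = {
        "subject_id": truth.subject_id,
        "lf_phase0_deg": truth.lf_phase0_deg,
        "hf_phase0_deg": truth.hf_phase0_deg,
        "so_phase0_deg": truth.so_phase0_deg,
        "so_events": truth.so_events.to_dict(orient="records"),
        "spindles": truth.spindles.to_dict(orient="records"),
        "tones": truth.tones.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(d, indent=1, default=float))
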