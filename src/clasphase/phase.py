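"""Instantaneous phase extraction, circular binning, and binary
upstate/downstate condition machinery.

Phase convention: the Hilbert analytic angle is shifted by +90° so that
-90° falls at signal troughs, 0° at negative-to-positive zero crossings,
and +90° at peaks.  Phases are degrees in [-180, 180) everywhere outside
this module; radians only transiently inside computations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import hilbert

__all__ = [
    "wrap_deg", "instantaneous_phase", "phase_at", "PhaseBinGrid",
    "bin_membership", "classify_state", "assign_conditions",
    "CONDITION_LABELS", "condition_spec", "matches_condition",
]

# the eight analyzed phase-locking conditions over (EEG SO, HR-LF, HR-HF);
# '-' = no phase-locking on that signal, 'U' = upstate, 'D' = downstate
CONDITION_LABELS = ("---", "U--", "-U-", "--D", "UU-", "U-D", "-UD", "UUD")


def wrap_deg(phi):
    """Wrap degrees into [-180, 180)."""
    return (np.asarray(phi, dtype=float) + 180.0) % 360.0 - 180.0


def instantaneous_phase(signal: np.ndarray, fs: float,
                        valid_mask: Optional[np.ndarray] = None,
                        pad_s: float = 10.0) -> np.ndarray:
    """Corrected Hilbert phase (degrees) of a narrowband, mean-free signal.

    Computed independently on each contiguous valid run (per the mask) with
    reflection padding to suppress edge transients; invalid samples and
    runs too short to pad are NaN.
    """
    x = np.asarray(signal, dtype=float)
    if not np.any(x):
        raise ValueError("phase of an all-zero signal is undefined")
    valid = np.ones(len(x), dtype=bool) if valid_mask is None \
        else np.asarray(valid_mask, dtype=bool)
    out = np.full(len(x), np.nan)
    pad = int(round(pad_s * fs))
    idx = np.flatnonzero(np.diff(np.r_[False, valid, False].astype(int)))
    for a, b in zip(idx[::2], idx[1::2]):
        seg = x[a:b] - x[a:b].mean()
        p = min(pad, len(seg) - 1)
        if len(seg) < 4:
            continue
        padded = np.r_[seg[p:0:-1], seg, seg[-2:-p - 2:-1]]
        ana = hilbert(padded)[p:p + len(seg)]
        out[a:b] = wrap_deg(np.degrees(np.angle(ana)) + 90.0)
    return out


def phase_at(phase_deg: np.ndarray, t0: float, fs: float,
             event_times: Sequence[float]) -> np.ndarray:
    """Nearest-sample phase lookup; events outside the span give NaN."""
    events = np.asarray(event_times, dtype=float)
    idx = np.round((events - t0) * fs).astype(int)
    out = np.full(len(events), np.nan)
    inside = (idx >= 0) & (idx < len(phase_deg))
    if np.any(~inside):
        warnings.warn(f"{int(np.sum(~inside))} event(s) outside the phase "
                      "series span; returning NaN for them")
    out[inside] = phase_deg[idx[inside]]
    return out


@dataclass(frozen=True)
class PhaseBinGrid:
    """Overlapping circular bins: 60° wide, stepped by 15° (24 bins).

    Membership uses the half-open convention (left, left + width], so each
    phase belongs to exactly width/step = 4 bins and the bins tile the
    circle.
    """
    width_deg: float = 60.0
    step_deg: float = 15.0

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.step_deg))

    @property
    def lefts(self) -> np.ndarray:
        return -180.0 + self.step_deg * np.arange(self.n_bins)

    @property
    def centers(self) -> np.ndarray:
        return wrap_deg(self.lefts + self.width_deg / 2.0)

    def membership_matrix(self, phi: np.ndarray) -> np.ndarray:
        """(n_events, n_bins) boolean membership for a vector of phases."""
        rel = (np.asarray(phi, dtype=float)[:, None]
               - self.lefts[None, :]) % 360.0
        return (rel > 0) & (rel <= self.width_deg)


def bin_membership(phi: float, grid: PhaseBinGrid) -> List[int]:
    """Indices of the bins containing ``phi`` (exactly 4 on the default grid)."""
    if not (-180.0 <= phi < 180.0):
        raise ValueError(f"phase {phi} outside [-180, 180)")
    return list(np.flatnonzero(grid.membership_matrix(np.array([phi]))[0]))


def classify_state(phi: float) -> str:
    """'D' (downstate) for phi in [-180, 0), 'U' (upstate) for [0, 180)."""
    return "U" if phi >= 0.0 else "D"


def condition_spec(label: str) -> Tuple[str, str, str]:
    """Parse a condition label like 'U-D' into per-signal requirements."""
    if len(label) != 3 or any(c not in "UD-" for c in label):
        raise ValueError(f"invalid condition label {label!r}")
    return tuple(label)  # type: ignore[return-value]


def matches_condition(states: Sequence[str], label: str) -> bool:
    """A tone matches iff every constrained slot equals the tone's state."""
    return all(req == "-" or req == st
               for req, st in zip(condition_spec(label), states))


def assign_conditions(phases: Sequence[float],
                      labels: Sequence[str] = CONDITION_LABELS) -> List[str]:
    """Labels (from ``labels``) matched by a (φ_so, φ_lf, φ_hf) triple."""
    triple = [classify_state(p) for p in phases]
    return [lab for lab in labels if matches_condition(triple, lab)]
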