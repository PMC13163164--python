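"""Configuration objects for the simulator and the analysis pipeline.

All tunable parameters of the study design live here with their default
values: filter bands, slow-oscillation and spindle criteria, the 10 Hz
heart-rate grid, the 60°/15° circular binning, Monte Carlo settings, and
the synthetic-cohort generator settings.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["ConfigError", "SimConfig", "AnalysisParams", "RunConfig"]


class ConfigError(ValueError):
    """Raised when a configuration field is invalid; names the field."""


@dataclass
class SimConfig:
    """Parameters of the synthetic polysomnography cohort.

    Amplitudes are μV for EEG and bpm for heart rate; times are seconds.
    ``preferred_phase_*`` are the oscillation phases (degrees, [-180, 180))
    at which the tone-evoked slow-oscillation response is largest; the
    evoked peak-to-peak amplitude of a tone with true onset phases
    (φ_so, φ_lf, φ_hf) is

        evoked_base_amp + Σ_c evoked_gain_c · cos(φ_c − preferred_phase_c)

    clipped at zero from below.
    """

    n_subjects: int = 20
    duration_s: float = 7200.0
    fs_eeg: float = 256.0
    fs_ecg: float = 256.0

    # EEG background and spontaneous events
    background_slope: float = 1.0     # 1/f^slope exponent of the noise floor
    noise_sd: float = 15.0            # SD of the 1/f background, μV
    so_rhythm_amp: float = 50.0       # amplitude of the continuous ~0.8 Hz rhythm, μV
    so_freq: float = 0.8              # Hz, slow-oscillation rhythm frequency
    so_rate: float = 8.0              # spontaneous SO events per minute of N2/N3
    so_amp_mean: float = 180.0        # spontaneous SO peak-to-peak amplitude, μV
    so_amp_sd: float = 15.0
    spindle_rate: float = 3.0         # spontaneous spindles per minute of N2/N3
    spindle_freq: float = 13.0        # Hz, within 11-16
    spindle_amp: float = 25.0         # peak envelope amplitude, μV

    # heart rate
    hr_mean: float = 60.0             # bpm
    lf_freq: float = 0.1              # Hz, within 0.04-0.15
    hf_freq: float = 0.25             # Hz, within 0.15-0.4
    lf_amp: float = 3.0               # bpm
    hf_amp: float = 2.0               # bpm
    ecg_noise_mv: float = 0.01

    # tones and evoked responses
    tone_interval_min: float = 15.0
    tone_interval_max: float = 30.0
    evoked_base_amp: float = 180.0    # μV peak-to-peak
    evoked_gain_so: float = 20.0      # μV per unit cosine
    evoked_gain_lf: float = 10.0
    evoked_gain_hf: float = 10.0
    preferred_phase_so: float = 75.0  # degrees
    preferred_phase_lf: float = 60.0
    preferred_phase_hf: float = -120.0
    evoked_latency_s: float = 1.2
    evoked_amp_sd: float = 0.0        # extra per-tone amplitude jitter, μV

    # tone-evoked spindles: Bernoulli with p = base + gain*cos(phi_so - pref_so)
    evoked_spindle_base_prob: float = 0.35
    evoked_spindle_gain_so: float = 0.2

    # tone-evoked heart-rate transient, amplitude depends on SO phase
    evoked_hr_base_bpm: float = 2.0
    evoked_hr_gain_so: float = 1.0
    preferred_phase_hr_so: float = 45.0

    arousal_rate_per_h: float = 5.0
    seed: int = 0

    def validate(self) -> "SimConfig":
        if not self.tone_interval_min < self.tone_interval_max:
            raise ConfigError(
                "tone_interval_min must be < tone_interval_max "
                f"(got {self.tone_interval_min} >= {self.tone_interval_max})"
            )
        for name in ("preferred_phase_so", "preferred_phase_lf",
                     "preferred_phase_hf", "preferred_phase_hr_so"):
            v = getattr(self, name)
            if not (-180.0 <= v < 180.0):
                raise ConfigError(f"{name} must lie in [-180, 180) (got {v})")
        strictly_positive = (
            "duration_s", "fs_eeg", "fs_ecg", "hr_mean", "lf_freq", "hf_freq",
            "so_freq", "spindle_freq", "tone_interval_min",
        )
        for name in strictly_positive:
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be strictly positive "
                                  f"(got {getattr(self, name)})")
        nonnegative = (
            "n_subjects", "noise_sd", "so_rhythm_amp", "so_rate", "so_amp_mean",
            "so_amp_sd", "spindle_rate", "spindle_amp", "lf_amp", "hf_amp",
            "evoked_base_amp", "evoked_latency_s", "arousal_rate_per_h",
            "evoked_amp_sd", "ecg_noise_mv",
        )
        for name in nonnegative:
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0 "
                                  f"(got {getattr(self, name)})")
        if not (11.0 <= self.spindle_freq <= 16.0):
            raise ConfigError(
                f"spindle_freq must lie in [11, 16] Hz (got {self.spindle_freq})")
        return self


@dataclass
class AnalysisParams:
    """Analysis-stage parameters with the study's defaults."""

    # EEG filters (Hz) and artifact rule
    broadband: tuple = (0.1, 30.0)
    so_band: tuple = (0.5, 4.0)
    spindle_band: tuple = (11.0, 16.0)
    filter_order: int = 4
    artifact_segment_s: float = 8.0
    artifact_amp_uv: float = 1500.0
    artifact_sd_z: float = 10.0

    # slow-oscillation criteria
    so_trough_max_uv: float = -80.0
    so_p2p_min_uv: float = 140.0
    so_dur_min_s: float = 0.25
    so_dur_max_s: float = 2.5
    so_min_p2p_filter_uv: Optional[float] = None  # optional size stratification

    # spindle criteria
    spindle_percentile: float = 88.86
    spindle_rms_window_s: float = 0.2
    spindle_dur_min_s: float = 0.3
    spindle_dur_max_s: float = 3.0
    spindle_min_oscillations: int = 5

    # spectra
    welch_segment_s: float = 4.0
    psd_grid_max_hz: float = 20.0
    psd_grid_step_hz: float = 0.1
    swa_band: tuple = (0.5, 4.0)

    # ECG / heart rate
    ecg_band: tuple = (0.5, 35.0)
    hr_grid_hz: float = 10.0
    rr_z_max: float = 10.0
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.4)
    hr_edge_s: float = 30.0

    # trial selection
    guard_s: float = 10.0             # ±window for artifact/arousal/stage checks
    unstim_min_gap_s: float = 20.0
    evoked_so_max_latency_s: float = 2.5
    swa_window_s: float = 8.0
    hr_response_window_s: float = 10.0

    # phase binning and statistics
    bin_width_deg: float = 60.0
    bin_step_deg: float = 15.0
    n_mc: int = 200
    n_resamples: int = 200
    resample_frac: float = 2.0 / 3.0
    alpha: float = 0.05
    min_trials: int = 5
    min_subjects: int = 3

    # condition analysis
    erp_window_s: tuple = (-2.0, 10.0)
    erp_extrema_window_s: tuple = (0.0, 3.0)


@dataclass
class RunConfig:
    """A full, serializable pipeline run: inputs, parameters, seed, outputs."""

    sim: SimConfig = field(default_factory=SimConfig)
    params: AnalysisParams = field(default_factory=AnalysisParams)
    seed: int = 0
    outdir: str = "results/run"
    input_dir: Optional[str] = None   # if set, read EDF/CSV instead of simulating
    use_ecg: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = SimConfig(**d.pop("sim", {}))
        params = d.pop("params", {})
        params = AnalysisParams(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in params.items()
        })
        return cls(sim=sim, params=params, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
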