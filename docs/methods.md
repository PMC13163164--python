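# Methods

This note documents the models, conventions, and numerical choices behind
`clasphase`: what the synthetic cohort emulates, how each analysis stage
is defined, where the design was genuinely open and what was decided.

## The analysis problem

Auditory tones delivered in N2/N3 sleep evoke slow-oscillation (SO)
responses whose size depends on *when* the tone lands relative to ongoing
rhythms: the EEG slow oscillation (~0.8 Hz) and the low- and
high-frequency oscillations of instantaneous heart rate (HR-LF,
0.04–0.15 Hz; HR-HF, 0.15–0.4 Hz). The pipeline quantifies that
dependence two ways: a *continuous* analysis that bins tones by the
instantaneous phase of each oscillation at onset, and a *multidimensional*
analysis that dichotomizes each oscillation into upstate/downstate and
compares the eight resulting phase-locking conditions.

## Synthetic cohort

The generator produces, per subject: a block-structured hypnogram
(guaranteed ≥ 60% N2/N3; not a model of real sleep architecture), arousal
intervals (default 5/h, 5–15 s), tones at uniform random 15–30 s intervals
dropped outside N2/N3, an EEG channel, and an ECG channel. Everything is
drawn from `numpy.random.Generator` seeded by (cohort seed, subject
index), so recordings are bit-reproducible.

**EEG.** The channel is the sum of 1/f^slope Gaussian background (default
SD 15 μV, slope 1), a continuous 0.8 Hz rhythm (default amplitude 50 μV —
large enough to carry a clean Hilbert phase, small enough that the rhythm
alone never satisfies the SO detection criteria), discrete SO events,
spindle bursts (Hann-windowed 13 Hz sinusoids, 0.5–1.5 s, 25 μV), and
tone-evoked responses.

SO events — spontaneous and evoked — are Gaussian-derivative
(K-complex-like) trough-then-peak waveforms with a 55%/45% trough/peak
split of the peak-to-peak amplitude. Three deliberate choices make the
ground truth recoverable by the downstream detectors:

1. *Band pre-compensation.* The 0.5–4 Hz zero-phase band-pass the SO
   detector operates on attenuates a one-cycle transient. The
   Gaussian-derivative shape keeps that attenuation to ~7% (a plain
   single sine cycle loses ~18%), and injected amplitudes are divided by
   the numerically computed attenuation factor, so the detector reads the
   nominal peak-to-peak amplitude (verified to ±8 μV at low noise).
2. *Phase reset.* The continuous rhythm is tapered to zero while each SO
   event plays out. Without this, the random alignment of rhythm and
   event adds a ±2·(rhythm amplitude) phase-locked confound to measured
   amplitudes that swamps the injected cosine gains.
3. *Refractoriness.* Spontaneous SOs and spindles keep clear of each
   tone's response window, so evoked responses are measured in isolation
   and the STIM and UNSTIM spindle baselines match.

Tone-evoked SOs start a fixed 1.2 s after onset. The latency is a free
parameter of the design; 1.2 s puts the 180 μV waveform far enough from
the onset sample that the acausal footprint of zero-phase filtering and
the Hilbert transform no longer biases the measured onset phase (bias
< 3°, versus ~30° at 0.5 s), while the evoked trough (onset + 1.65 s)
stays inside the 2.5 s evoked-SO attachment window. Evoked amplitudes
follow the additive cosine law stated in the README over the *true*
phases — the analytic phases of the noise-free rhythm and of the LF/HF
modulators — clipped at zero. Tone-evoked spindles are injected after the
evoked trough with probability 0.35 + 0.2·cos(φ_so − 75°); 0.35 matches
the probability of a spontaneous spindle in a 10 s window at the default
3/min rate, so only the SO-phase coupling separates STIM from UNSTIM.

**ECG.** Instantaneous heart rate is HR(t) = 60 + 3·sin(2π·0.1·t) +
2·sin(2π·0.25·t) bpm (plus a 4 s half-sine tone-evoked transient whose
amplitude depends on SO phase, default 2 ± 1 bpm). Beat times integrate
RR = 60/HR with RR anchored at each interval's *end* beat via a fixed
point, so the analysis convention (HR assigned at interval end beats)
recovers HR(t) exactly at beat instants — LF/HF amplitude errors through
the full chain are 0.04%/3.8% and Hilbert-phase errors < 1°. Beats are
template waveforms (narrow 1 mV R spike plus small Q/S/T deflections);
realism beyond R-peak detectability is not attempted.

**Free parameters.** Values neither analysis conventions nor the response
law pin down were chosen once for a high-SWA adolescent-like N3 profile
and kept: spontaneous SO rate 8/min of N2/N3 (also what makes UNSTIM
windows — which require a spontaneous SO within 2.5 s of the midpoint —
reasonably frequent), spontaneous SO peak-to-peak 180 ± 15 μV, spindle
rate 3/min. A 2 h recording yields roughly 220 STIM and 40 UNSTIM trials
per subject, a ratio comparable to overnight cohorts once scaled.

**Trial-level generator.** `simulate_trial_table` draws tone trials
directly from the response model (uniform phases, cosine-law STIM
responses plus Gaussian residuals, phase-independent UNSTIM responses)
without waveform synthesis. It exists for statistical calibration at many
seeds — type-I error of the bin tests, enhancement-ordering stability —
where signal-level simulation adds nothing but runtime.

**What the generator does not emulate.** Realistic sleep cycling, EEG
nonstationarity across the night, SO trains and K-complex/SO distinction,
spindle frequency chirp, respiratory sinus arrhythmia coupling to actual
respiration, ectopy, or movement artifacts beyond the injected arousal
intervals. Passing tests therefore demonstrate that the *analysis chain*
is correct and calibrated on data satisfying its assumptions — not that
the physiological effect exists in any particular real dataset.

## Analysis conventions

- **Filters** are 4th-order Butterworth applied forward and backward
  (`sosfiltfilt`); all stated bands refer to the single-pass design.
- **Artifacts**: 8 s segments are flagged when any sample exceeds
  ±1500 μV or the segment SD's robust z-score (median/MAD) exceeds 10.
  The robust scale is deliberate: with a plain mean/SD the z-score of one
  extreme segment among n is algebraically bounded by ~√n, so a single
  gross artifact in a long recording could never reach the threshold.
- **SO detection**: candidates between successive downward zero
  crossings; strict inequalities on trough (< −80 μV) and peak-to-peak
  (> 140 μV), inclusive duration bounds (0.25–2.5 s). An optional minimum
  peak-to-peak filter supports amplitude stratification.
- **Spindles**: the envelope threshold is the 88.86th percentile of the
  0.2 s RMS envelope over all artifact-free N2/N3 samples, computed once
  per subject (a pooled, not per-window, reference). Because the 0.2 s
  smoothing widens every supra-threshold episode by roughly the window
  length, event boundaries are refined as the maximal contiguous run of a
  short (0.04 s, about half a spindle cycle) RMS envelope above the same
  threshold through the episode's peak; duration bounds (0.3–3 s,
  inclusive) apply to the refined extent, while cycle counting (≥ 5 full
  cycles between upward zero crossings) and the spectral check use the
  full episode. The spectral check computes 6-cycle complex-Morlet power
  at 10–20 Hz in 0.5 Hz steps, averaged over the episode, and requires
  exactly one strict *interior* local maximum inside 11–16 Hz with all
  power above 16 Hz strictly below it — a maximum sitting on the band
  edge, as produced by monotonically decreasing 1/f background, does not
  qualify.
- **Spectra**: Welch with 4 s Hann segments and 50% overlap, linearly
  interpolated to a 0.1 Hz grid; "total power" means the mean over the
  0–20 Hz grid; per-subject normalization divides by the mean total power
  across all stimulated windows, so that quantity averages to exactly 1.
  SWA is the mean normalized power over 0.5–4 Hz.
- **Heart rate**: cubic-spline interpolation uses natural boundary
  conditions — the default not-a-knot end conditions overshoot the
  beatwise range at record edges. The first and last 30 s of the LF/HF
  phases are treated as unreliable and excluded from event lookups.
- **Phase convention**: phase = Hilbert analytic angle + 90°, wrapped to
  [−180°, 180°); computed per contiguous artifact-free run with 10 s
  reflection padding. 0° belongs to the upstate (half-open state
  intervals), and bin membership on the 60°/15° grid uses the half-open
  convention (left, left + 60°], under which every phase falls in exactly
  four bins.
- **Trial selection**: the entire ±10 s window must lie in N2/N3 and be
  free of artifacts and arousals (the stricter whole-window reading of
  the stage rule). One UNSTIM per maximal tone-free interval (its
  midpoint), never a tiling. UNSTIM windows may overlap neighboring STIM
  windows: with tones every 15–30 s and ≥ 20 s tone-free intervals this
  is unavoidable, and the UNSTIM window itself never contains a tone.

## Statistics

Responses are mean-centered within subject and condition (STIM and UNSTIM
separately), which removes both subject offsets and the overall
stimulation main effect, isolating phase structure. Per subject and bin,
the Monte Carlo baseline is 200 draws from a normal with the bin's UNSTIM
mean and variance (ddof = 1); bins need ≥ 5 STIM trials and ≥ 2 UNSTIM
values, and the draws are seeded per (analysis seed, subject, bin). The
group test per bin is a one-sample t-test on the paired difference
(STIM−MC) − (UNSTIM−MC) across subjects — the separate STIM−MC and
UNSTIM−MC means are also reported — with BH-FDR over the 24 bins of one
signal × metric family (families are never pooled). Bins with fewer than
3 contributing subjects are reported untested and excluded from the
family.

The PRI uses the 200-value distribution (stim_mean − mc_draw_k) per bin;
for every bin pair the sign of the Welch t-statistic (Satterthwaite df,
sign(0) = 0) enters both bins' averages antisymmetrically, so PRIs sum to
zero absent exact ties. Spindle likelihood uses a pooled-UNSTIM null per
bin: 200 resamples of ⌊2n/3⌋ trials without replacement, geometric mean
with a 1/(2m) continuity floor for zero-likelihood iterations; per-subject
STIM and UNSTIM likelihoods relative to the null are compared with
Welch's t. Strategy comparisons in the multidimensional analysis test
per-subject differences with a paired t-test when Shapiro–Wilk (α = 0.05)
does not reject normality, Wilcoxon signed-rank otherwise.

Type-I calibration: on zero-gain trial-level cohorts the bin contrast
test's raw p-values are uniform (pooled KS) and the mean fraction of
FDR-significant bins is ~2%.

## Problem sizes

Desk-scale defaults throughout: the recovery analyses use 20 subjects ×
2 h (the test suite and acceptance script), the calibration and ordering
checks use 12-subject trial-level cohorts over 10–20 seeds, and the demo
drivers use 3–16 subjects. These sizes were chosen so the full chain —
including per-subject signal synthesis at 256 Hz — completes in minutes
while leaving every statistic comfortably powered for the injected effect
sizes (gains 20/10/10 μV against ~15 μV trial-level residual noise).

## Known limitations

- The argmax bin of the group contrast is a noisy estimator of the
  preferred phase: 60° bins stepped by 15° are heavily correlated and the
  cosine response is flat near its peak, so the maximal bin can sit one
  or two steps from the injected optimum even when the significant-bin
  set brackets it. A weighted circular fit would be sharper; the binned
  readout was kept because it is the field's convention.
- Evoked-SO attachment takes the first detected SO trough within 2.5 s,
  so strongly anti-optimal tones whose evoked amplitude falls near the
  detection threshold are occasionally lost — a selection effect that
  mildly censors the response curve's minimum (it exists in the real
  protocol too, where non-optimal phases evoke fewer SOs).
- UNSTIM windows are not balanced across sleep cycles or across the
  night.
- The spindle-likelihood test needs ≥ 5 STIM and ≥ 5 UNSTIM trials per
  subject-bin; with realistic UNSTIM counts many bins are carried by a
  subset of subjects.
- EDF export quantizes to 16 bits over each channel's observed range
  (~0.02 μV steps for typical EEG); round-tripping through EDF is
  lossless for every analysis here but not bit-identical.
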