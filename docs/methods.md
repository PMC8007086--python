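# Methods

This note documents the models, numerical choices and limitations behind
the `phonation` package: a pipeline that extracts glottal perturbation
features from sustained phonemes (/a/, /o/, /m/), compares them across a
three-group cohort (healthy controls, Parkinson's patients off and on
levodopa), and classifies the groups with RBF-kernel SVMs — all
exercised end-to-end on a synthetic voice cohort with known ground
truth.

## Signal model and feature definitions

A sustained phonation is modelled as a quasi-periodic train of glottal
pulses. Pulse instants `t_i` define instantaneous periods
`T_i = t_{i+1} − t_i` and per-period peak amplitudes `A_i`. From a
voiced segment we compute, per phoneme, twelve classifier features:

- **Jitter** (period perturbation): `abs` = mean |T_{i+1} − T_i|
  (seconds); `rel` = abs / mean T; `rap` and `ppq5` = mean absolute
  deviation of `T_i` from its centred 3-point (resp. 5-point) moving
  mean, divided by mean T.
- **Shimmer** (amplitude perturbation): `dB` = mean |20 log10(A_{i+1}/A_i)|;
  `rel` = mean |A_{i+1} − A_i| / mean A; `apq3`, `apq5`, `apq11` =
  moving-mean deviations as for jitter with windows 3, 5 and 11.
- **Pitch std**: sample standard deviation (n−1 denominator) of
  `f0_i = 1/T_i`.
- **Harmonicity**: with `r` the normalized autocorrelation value at the
  pitch lag, `HNR = 10 log10(r / (1 − r))` dB and `NHR = 1 − r`.

Mean, median, max and min pitch are computed as well but kept out of the
classifier feature block: they carry strong speaker/sex information that
would dominate group classification. All ratio features are stored as
dimensionless fractions; percent formatting is a presentation concern.
Logarithms are base 10 throughout (dB conventions). A feature whose
minimum period count is not met (e.g. `apq11` with N < 11) is reported
missing, and a subject with any missing classifier value is dropped
whole so the N_subjects × 10 row structure of the matrices stays exact.

## Pulse detection

The study protocol this package follows used an external tool for pulse
marking; here detection is deterministic and self-contained:

1. a segment-level normalized autocorrelation fixes the expected period
   (pitch search range 60–400 Hz by default, configurable); a segment
   whose pitch peak falls below the voicing threshold (default 0.3) is
   declared unvoiced;
2. pulse peaks are picked one expected period apart (±30% search
   window) walking outward from the strongest waveform sample; end
   picks that land on the noise floor (clipped search windows at the
   segment boundary) are stripped by a 0.25×median-amplitude check;
3. each period is refined to sub-sample precision by parabolic
   interpolation of the *normalized cross-correlation* between
   consecutive cycles. A parabola on the rectified peak itself is
   biased when the glottal peak is asymmetric (curvature differs left
   and right of the maximum); the cross-correlation of two copies of
   the same pulse shape peaks symmetrically at the true lag, and the
   energy normalization removes the bias a truncating window would
   otherwise introduce near segment boundaries. On clean synthetic
   trains this recovers periods to well under one sample at any f0 in
   the search range.

Per-period amplitude is the peak absolute sample in the first 70% of
the period starting at `t_i`; the final 30% is excluded because the next
pulse's onset already rises there and would otherwise leak `A_{i+1}`
into `A_i`.

## Autocorrelation normalization

`normalized_autocorrelation` divides by the lag-0 energy of the
mean-removed segment, so `r[0] = 1` and `|r[k]| ≤ 1` (the "biased"
estimator). This estimator tapers linearly with lag: on a perfectly
periodic 0.5 s segment at 200 Hz the pitch peak cannot exceed
`1 − T0/L = 0.99`, which would floor NHR at 0.01 regardless of voice
quality. The feature-extraction pipeline therefore enables the
`unbiased` flag (each lag rescaled by `L/(L−k)`) when computing
harmonicity, so HNR/NHR reflect the noise content rather than the
segment length. The unbiased peak can marginally exceed 1 on noiseless
periodic input; HNR is then capped at a ceiling (default 40 dB) with a
warning. Near-equal autocorrelation peaks at period multiples (exact on
noiseless input once the taper is removed) are resolved toward the
smallest lag, i.e. the fundamental.

## Synthetic cohort generator

The generator exists so every downstream stage is testable with known
ground truth; it emulates the study design (22 controls; 24 patients
recorded off- and on-medication; three phonemes; ≥ 5 s recordings at
48 kHz, 16-bit mono WAV).

**Source.** A Rosenberg-type glottal pulse (cosine rise over 0.40/f0,
cosine fall over 0.16/f0, written out analytically) is placed at
continuous — sub-sample — instants, so the returned ground-truth pulse
sequence is exact rather than grid-quantized. Cycle periods are
`(1/f0)(1 + ε_i)` and peak amplitudes `A0(1 + δ_i)` with `ε, δ` i.i.d.
zero-mean Gaussians (std = `jitter_sigma`, `shimmer_sigma`), both
clamped at 6σ so periods and amplitudes stay positive; parameter
combinations for which the clamp could not guarantee positivity are
rejected at construction.

**Vocal tract.** Cascaded two-pole resonators with textbook formant
targets: /a/ 800/1200 Hz, /o/ 450/900 Hz, /m/ a single 250 Hz resonance
plus −12 dB/octave extra tilt (one-pole low-pass sections referenced at
500 Hz). Pole angles are adjusted so each section's magnitude response
peaks exactly at its centre frequency. The filtered waveform is rescaled
to a 0.5 peak before noise is added — formant filtering attenuates the
open vowels heavily and would otherwise waste 16-bit headroom;
perturbation features are scale-invariant so the ground truth is
untouched.

**Aspiration noise.** White Gaussian noise at a prescribed
signal-to-noise ratio in dB (`+inf` = noiseless).

**Cohort structure.** Per-subject parameters are drawn from per-group
truncated-normal distributions. Defaults (all invented, and labelled
`synthetic` in the manifest — the study reports significance directions,
not effect sizes):

| group  | jitter σ       | shimmer σ     | aspiration SNR (dB) |
|--------|----------------|---------------|---------------------|
| CO     | 0.005 ± 0.003  | 0.03 ± 0.015  | 22 ± 4              |
| PD-off | 0.012 ± 0.006  | 0.06 ± 0.03   | 15 ± 4              |

The distributions overlap substantially on purpose: heavily overlapping
classes are what make the classification problem realistic rather than
trivial. f0 is a subject trait (140 ± 25 Hz, shared across medication
states). The PD-on state is the same subject's PD-off draw pulled toward
the control-group mean by a per-subject response fraction drawn from
N(0.35, 0.3) truncated to [−0.25, 1]. Two aspects of that choice matter:

- *mean response 0.35, not 0.5*: at the exact midpoint the on-state is
  equidistant from both other groups and the relative difficulty of the
  CO-vs-PD-on and off-vs-on contrasts is a coin flip; a response short
  of halfway keeps the medicated state closer to the unmedicated one,
  which is the regime the three-way AUC pattern of the emulated study
  implies.
- *response heterogeneity with possible non-responders*: levodopa
  effects on voice are notoriously inconsistent across patients; the
  spread (and the small negative tail) is what makes the off-vs-on
  contrast the hardest of the three, as observed clinically.

**What the generator does not emulate** — and hence what passing tests
do *not* show about real recordings: tremor (low-frequency f0 and
amplitude modulation), breath groups and onset/offset dynamics, vocal
fry and subharmonics, room acoustics and microphone coloring,
correlated (pink) aspiration noise, and any articulatory detail beyond
two formants and a tilt. Results on this cohort validate the *pipeline*,
not clinical effect sizes.

## Dataset protocol

Recordings are trimmed to the longest contiguous region whose 25 ms
frame energy exceeds 10% of the median frame energy (an automated
stand-in for manual removal of silences), then cut into ten contiguous
non-overlapping 0.5 s segments from the trimmed start (an evenly-spread
alternative is provided; recordings under 5 s are rejected). One row per
(subject, segment); 12 features × phoneme, phoneme-major column order.
The full default cohort yields a 220 × 36 control block and 240 × 36
blocks for each medication state.

## Statistics

Anderson-Darling screens normality (5% critical value, normal family
with estimated parameters). Group contrasts are two-sided
nonparametric tests at α = 0.05: Wilcoxon signed-rank for the paired
medication contrast (rows paired by subject and segment; zero
differences dropped, tied absolute differences mid-ranked) and
Mann-Whitney U for the two disease contrasts. The signed-rank exact
null distribution is computed by a generating-function (shift)
algorithm over doubled mid-ranks for up to 25 retained pairs — exact
p-values therefore remain available for tied data — with scipy's
tie-corrected, continuity-corrected normal approximation above.
Mann-Whitney uses the exact distribution when the smaller group has ≤ 8
observations and the pooled data are tie-free, the corrected
approximation otherwise. No multiple-testing correction is applied by
default (mirroring the emulated protocol); a Holm option is available.

Segments are treated as independent observations by default, exactly as
the row structure implies; this is pseudo-replication (ten segments per
subject are highly correlated) and inflates significance, so a
`aggregate='subject'` mode that tests subject means is provided and
recommended for honest inference.

## Classification

Seven RBF-kernel SVMs per contrast, one per non-empty phoneme subset
{a, o, m, a+o, a+m, o+m, a+o+m}, each using that subset's 12 features
per phoneme. Evaluation is stratified 5-fold cross-validation (each
fold an 80/20 train/test split); features are z-scored on the training
fold only; the kernel width uses the median-heuristic
(γ = 1/(2·median²) of training pairwise distances, deterministic), C = 1,
no hyperparameter search. Confusion counts use the decision-function
sign; ROC and AUC are computed on pooled out-of-fold scores, with AUC in
its rank (Mann-Whitney) form — ties counted half. The positive class is
the more-affected state (PD-off against either other group, PD-on
against CO), so sensitivity reads as "detecting disease / the off
state".

Split granularity defaults to `segment`, which scatters a subject's ten
segments across folds and lets the classifier partly learn speaker
identity — optimistic, but it replicates the emulated protocol's random
segment picking. `subject` granularity (all segments of a subject share
a fold, via grouped stratified folds) gives the honest generalization
estimate and is exposed everywhere.

## Problem sizes and tolerances

The default verification workloads were sized to be decisive yet quick:
the full 22/24-subject cohort (210 recordings, 2 100 segments) for the
shape and ordering checks; three 30 s trains for jitter recovery against
the closed form E|T_{i+1}−T_i| = 2σ_T/√π (10% tolerance — Monte-Carlo
error at ~3 000 periods is ~2%); 200 feature-level null-cohort
replicates for the 5% ± 3% type-I check; 200 label permutations
(120 × 12 matrix) for the chance-AUC check (0.5 ± 0.05). Exact-formula
checks assert at 1e-9 relative; enumeration oracles for the rank tests
cover all n ≤ 8 inputs, including ties for the signed-rank test.

## Known limitations

- Pulse marking is not byte-compatible with any external tool's marks;
  only the printed feature definitions are reproduced exactly.
- The trimming heuristic assumes a recording that is mostly phonation;
  recordings dominated by silence would shift the median frame energy.
- The energy-based A_i convention measures the filtered waveform's peak,
  not glottal flow amplitude; shimmer on vowels is therefore modulated
  by formant ringing (consistently across groups).
- Feature-level null cohorts used for calibration are i.i.d. by
  construction; they calibrate the tests, not the audio pipeline.
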