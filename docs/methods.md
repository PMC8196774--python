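# Methods

This note documents the models, parameter choices and numerical decisions
behind `puretone`, and what the simulation-based validation does and does
not demonstrate.

## The adaptive staircase

One track estimates the hearing threshold for one ear at one frequency
using the modified Hughson-Westlake rule. The track has three phases:

1. *Initial ascent.* The first tone is presented at 30 dB HL. After each
   miss the level rises by 10 dB. A miss at the ceiling terminates the
   track with a NO_RESPONSE sentinel rather than a fabricated number.
2. *Descending runs.* After a heard response the level drops in 10 dB
   steps until a miss.
3. *Ascending runs.* After a miss the level rises in 5 dB steps until a
   heard response.

A *reversal* is any change of track direction. The turn from the initial
ascent into the first descent is counted as reversal 1; a miss while
descending and a heard response while ascending each log one more. The
threshold is the level of the first heard response in an ascending run at
a moment when at least three reversals have already been logged. With the
default parameters this means the second ascending-run confirmation seals
the threshold, giving the characteristic 8-presentation track for a
deterministic subject (30, 40, 30, 35, 40, 30, 35, 40 for a 40 dB HL
threshold).

Conventions the clinical description leaves open, fixed here:

- **Floor behaviour.** Heard responses clamp at −10 dB HL; a heard
  response at the floor during a descending run is treated as the
  turnaround point, so a subject who hears everything converges to −10.
- **Descending run length.** A heard response during a descent continues
  the descent in further 10 dB steps ("down until no response"), rather
  than switching to the ascent after a single drop.
- **Termination guarantee.** A hard cap of 50 presentations (an
  implementation safeguard, not part of the clinical rule) raises an
  error for non-converging response patterns; every level-deterministic
  subject terminates well under the cap.

Because the presented levels all lie on a 5 dB grid anchored at the 30 dB
HL start, the estimate for a deterministic subject is the smallest grid
level at or above the true threshold: recovery is exact on the grid and
biased upward by at most 4 dB (mean +2.5) off it. This quantization is
inherent to the 5 dB procedure, not an implementation artifact.

## Levels and classification

`dB SPL = dB HL + RETSPL(f)` converts between the normative hearing-level
scale and physical sound pressure, per transducer. Levels are carried as
reals throughout — calibration produces off-grid RETSPLs such as 7.3 dB
SPL — and only the staircase quantizes. Three RETSPL tables are packaged:
ER-3A insert earphones (the ANSI reference), and a smartphone-earphone
profile before (v1) and after (v2) median-difference calibration. A
plausibility bound |RETSPL| ≤ 50 dB is enforced on load.

ASHA severity bands label audiogram cells. The printed band edges
(severe 71–90, profound ≥ 90) overlap at 90 dB HL; this implementation
keeps 90 dB HL in *severe* and starts *profound* strictly above it,
preserving the stated severe upper bound. Thresholds below 0 dB HL
(better-than-normative hearing, possible down to the −10 dB HL floor)
classify as normal.

## Session policies

- **Order.** Right ear first, frequencies ascending 250 → 8000 Hz;
  configurable, since the clinical description requires only "sequential"
  testing.
- **Ceilings.** 75 dB HL at 250 Hz, 80 dB HL elsewhere, reflecting the
  maximum output of the calibrated smartphone-earphone combination.
- **Ambient noise.** The test pauses when the background level is
  *strictly* greater than 40 dB SPL (default, configurable). Pauses
  annotate metadata and freeze the track; recorded responses are never
  discarded.
- **Masking.** The minimum non-test-ear masking level is
  `presentation SPL − IA` with interaural attenuation IA = 40 dB by
  default (the minimum clinical assumption for air conduction); at or
  below the IA no masking is needed. The computation is always reported
  but only applied when enabled — normal-hearing testing does not need
  it.

## Virtual listeners

The response model maps presentation level to the probability of an
"I can hear it" press:

```
p(level) = guess + (1 − guess − lapse) · F(β · (level − threshold))
```

with F the standard logistic CDF. Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| threshold | per ear × frequency | 50% point of the underlying function, dB HL |
| β (slope) | 2.0 dB⁻¹ | psychometric steepness; logistic scale 1/β = 0.5 dB |
| guess | 0.01 | spurious presses far below threshold |
| lapse | 0.01 | misses far above threshold (includes instructed "unsure → can't hear it") |

The steepness default describes an attentive adult in a quiet booth doing
a near-threshold detection task: steep enough that the staircase's 5 dB
grid dominates the error budget, while the nonzero guess/lapse rates
exercise every stochastic code path. A `step` model (heard iff
level ≥ threshold, boundary inclusive) provides the deterministic limit.

Cohorts draw thresholds i.i.d. per ear × frequency from a normal
distribution (default mean 5 dB HL, SD 8 dB — a plausible pooled spread
for self-identified normal-hearing volunteers), rounded to 1 dB and
clamped to [−10, 120]. Real audiograms are correlated across frequencies
and ears; nothing in the method depends on that correlation, so it is not
modelled. No age structure, conductive-loss or noise-exposure models are
included.

`as_device_listener` models a miscalibrated device: if the assumed RETSPL
understates the true transducer output by Δ dB at some frequency, every
tone is played Δ dB softer than intended and the measured threshold rises
by exactly Δ. This is the linearity the calibration procedure relies on.

## Calibration

Per frequency, the correction is
`RETSPL_new = RETSPL_old − median_ears(HL_audiometer − HL_device)`.
The sign follows from the level equation: the device records HL_dev when
`HL_dev + RETSPL_assumed = HL_aud + RETSPL_true`, so
`RETSPL_true = RETSPL_assumed − (HL_aud − HL_dev)`. The median over an
even number of ears is the midpoint of the central pair, which is how
corrected tables acquire non-multiple-of-5 entries. Cells where either
instrument hit its ceiling carry no numeric threshold and are excluded
pairwise, with a logged count.

Agreement statistics: pooled Spearman rank correlation (average-rank tie
handling; exact permutation p-value below 10 pairs, large-sample t
approximation otherwise — rank-based because measured thresholds are
non-normal and outlier-prone) and per-frequency mean absolute error with
the SD of |error| (sample SD; defined as 0 for a single pair).

### Validation cohort design

The staircase reports on a 5 dB grid, so the median difference identifies
a RETSPL error only up to grid quantization: for adverse mixes of
threshold residues (mod 5) the median's bias can reach 4 dB, and large
negative errors push low apparent thresholds into the −10 dB HL floor,
censoring them. The calibration recovery validation therefore uses a
purpose-built deterministic cohort (`balanced_calibration_cohort`): 40
ears with thresholds between 11 and 33 dB HL alternating residues 1 and 3
(mod 5). The 50/50 residue balance makes the median's quantization bias
cancel to within ±2.5 dB for every integer injected error, and the
threshold range keeps all shifted values clear of the floor and ceilings
for errors up to ±15 dB. Under this design the corrected table recovers
the true RETSPLs within 2.5 dB at every frequency and post-calibration
MAE never exceeds pre-calibration MAE. On arbitrary cohorts (thresholds
near the floor, unbalanced residues) the recovery bound degrades for the
stated reasons; this is a property of the 5 dB procedure itself.

## Signals

- Tone amplitude: `10^((target − max_output)/20)` of full scale, where
  `max_output` is the measured 2-cc-coupler SPL of a full-scale sine for
  that device, channel and frequency. No interpolation between the six
  measured frequencies — off-grid requests are refused rather than
  guessed.
- Ramps: 20 ms raised-cosine onset/offset, shaping the "continuous tone"
  presentation without spectral splatter.
- Masking noise: Gaussian noise brick-wall band-limited in the frequency
  domain to one third of an octave around the test frequency (the
  clinical narrow-band convention), RMS-scaled to the requested SPL.
- Metering: unweighted RMS (no A-weighting is assumed for the ambient
  monitor), referenced to the SPL of a unit-RMS signal, which sits
  3.01 dB above the full-scale-sine calibration point. Rendering a tone
  and metering its steady-state segment round-trips within 0.1 dB; the
  residual comes from the window spanning a non-integer number of
  periods. Digital silence reports −∞ ("below floor").

## Problem sizes used in validation

The test suite and acceptance checks run entirely on synthetic data
generated at test time: brute-force staircase recovery sweeps every 5 dB
grid threshold at all six frequencies; calibration recovery simulates a
40-ear deterministic cohort for each of the 31 integer error values in
[−15, 15]; stochastic accuracy uses 100 logistic listeners (200 ears,
1200 tracks). These sizes were chosen to match the scale of a typical
single-site validation study while keeping the whole suite fast.

## Known limitations

- No bone conduction, speech audiometry, or coupler/ear simulation; the
  masking model is the linear crossover arithmetic only.
- The simulator's listeners are stationary (no fatigue, learning or
  attention drift) and frequency-uncorrelated, so passing validation
  demonstrates correctness of the procedure and calibration algebra, not
  field accuracy on human subjects.
- Fine-grained tracking modes (2 dB down / 1 dB up) and the
  "2-of-3 ascending responses" threshold variant are not implemented.
- Calibration assumes the reference audiometer is exact; its own
  measurement error folds into the recovered RETSPLs.
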