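# Methods

## Pipeline

`semgforce` estimates grasp force from multi-channel surface EMG and selects
the cheapest feature/electrode configuration that is statistically
indistinguishable from the best one. Stages: (1) segment the continuous
recording into grasp actions, (2) extract windowed time-domain features,
(3) evaluate every (position-set, feature-set) combination with a GRNN under
repeated action-wise splits, (4) score with NRMS/NMAE/CC, (5) group factor
levels with one-way ANOVA + Tukey HSD homogeneous subsets and apply the
minimal-cardinality rule.

## Synthetic recordings

The simulator emulates a prompted-grasp protocol: `n_actions` = 60 presses of
~1 s at strength levels 25/50/75/100% of `max_force` (250 N), 15 presses per
level in randomized order, separated by rests drawn uniformly from
0.5–1.5 s. Each press is a smooth ramp–plateau–ramp force profile (a Tukey
window with 10% cosine flanks) — steep enough for realistic onsets, smooth
enough that onset detection is not degenerate. The commanded level is
multiplied by a lognormal jitter (σ = 0.08) to mimic within-level
variability of voluntary contractions.

EMG on channel *c* is zero-mean Gaussian noise band-passed to 10–450 Hz
(4th-order Butterworth, zero-phase) and amplitude-modulated:

    std(t) = noise_floor + gain_c · (force(t)/max_force)^γ · envelope_scale

with defaults `noise_floor` = 8 µV RMS, `envelope_scale` = 300 µV,
γ = 1 (near-linear amplitude–force coupling, the standard first-order model
for isometric grasp; it also makes IEMG approximately linear in force, which
the recovery tests exploit). Default gains (1.0, 0.85, 0.7, 0.9, 0.75, 0.0)
give five informative channels and one pure-noise channel. A gain of zero
yields stationary noise uncorrelated with force — the planted "uninformative
electrode". The upper band edge is 450 Hz rather than the sensor's nominal
500 Hz because a digital band-pass requires the edge strictly below the
Nyquist frequency at the 1 kHz sampling rate.

What the simulator does **not** model: motor-unit structure, inter-channel
cross-talk, electrode shift, fatigue, or force-dependent spectral changes.
Channels are independent given the force. Passing tests therefore show the
pipeline recovers planted amplitude-coupling structure; they do not certify
performance on real recordings.

## Segmentation

Action onsets/offsets are found by thresholding force at 5% of the recording
maximum, merging gaps < 100 ms and dropping runs < 200 ms (the recorded
protocol had full relaxation between presses, so a force threshold is
faithful; EMG-based onset detection is out of scope). Each action span of
length T2 keeps relaxation flanks of floor(T2/4) samples on both sides,
clipped at recording boundaries and truncated at the midpoint between
adjacent actions so kept spans never overlap.

## Features and windows

200 ms windows with 50% overlap (N = 200 samples, step = 100 at 1 kHz).
Windows never straddle a segment boundary; trailing partial windows are
dropped; a segment shorter than one window is skipped with a warning. The
per-window regression target is the mean force over the same samples (the
mean smooths sensor noise and is the conventional target for envelope-scale
regression). Guard thresholds: 30 µV for ZC, 150 µV for WAMP. Feature-set
names concatenate letters in the fixed order V, I, W, Z; position sets join
labels sorted by index ("P1+P2+P5"), so report tables are directly
comparable across runs.

## GRNN

Training memorizes the standardized training patterns (per-column
center/scale learned on the training fold; constant columns get scale 1).
Prediction is the Gaussian-kernel weighted mean of training targets; the
row-wise minimum squared distance is subtracted before exponentiation so
distant queries cannot underflow to 0/0. Predictions are therefore always
convex combinations of training targets.

The spread σ is selected per (spec, repeat) on the training fold from a
logarithmic grid 10⁻²…10¹ (8 points) by a single action-wise inner hold-out
(leave-one-action-out when the fold has < 5 actions); a fixed numeric value
in `RunConfig.grnn_spread` bypasses selection. A fixed σ across input
dimensions 1–24 would systematically favor some dimensionalities, hence the
per-trial choice.

Splits are by action, never by window: overlapping windows of one action
share samples, and splitting windows would leak train data into the test
fold. The test side receives round(n/5) actions (at least 1). Per-trial RNG
streams derive from `SeedSequence([seed, spec_index, repeat])`, so the result
table is identical regardless of execution order.

## Metrics

NRMS uses the N−1 divisor inside the root mean square and normalizes by the
experiment-wide force range (f_max − f_min over the whole feature table, not
per fold), as does NMAE. CC is the Pearson correlation; when a test fold's
predictions or targets are constant, CC is undefined and recorded as missing
(NaN) with a log entry — this happens routinely for pure-noise channels
paired with the WAMP-only feature set, whose feature column is identically
zero.

## ANOVA and Tukey homogeneous subsets

One-way and balanced two-way ANOVA are computed from the textbook
sum-of-squares decompositions (the subset step needs MS_within and its df
directly). Degenerate inputs: zero within-group variance with distinct means
reports F = ∞, p = 0; fully constant data F = 0, p = 1.

Homogeneous subsets follow the convention of the major statistics packages:
order the level means (ascending for NRMS/NMAE, descending for CC) and
report every maximal run of consecutive levels whose extreme-mean range,
scaled by sqrt(MS_within/n), does not exceed the studentized-range critical
value q(α; k, df) with k = the total number of levels. With balanced
replicates this equals grouping by mutual pairwise non-significance (the
exhaustive oracle used in tests). Unbalanced groups (possible when CC is
missing for some repeats) use the harmonic mean n with a logged warning. The
reported within-subset "Sig." is the p-value of the subset's own range using
the subset's size; a singleton reports 1.0.

Selection: within the best subset, choose the level with minimal cardinality
(number of positions or features); ties break by the better mean, remaining
ties by canonical name order (logged). When the ANOVA is not significant at
α the grouping and selection are still produced but flagged
`significant = False`; with a single available level the level is returned
as trivially optimal with no ANOVA.

## Problem sizes and determinism

The default simulated study (60 actions, ~2 min of signal at 1 kHz) yields
roughly 770 windows; the full 945-spec × 10-repeat factorial on it runs in
minutes. The test suite and the acceptance script use scaled designs chosen
to exercise every code path at comfortable runtimes: a compact 24-row table
for the full-factorial count check, and 20-action recordings with two
planted informative channels and the {I, W, IW} feature grid for recovery
runs (189 specs × 5 repeats per seed, 10 seeds). All randomness flows from
explicit integer seeds; identical configuration reproduces bit-identical
artifacts.

## Known limitations

- The force-threshold segmenter assumes clean rest phases; co-contraction
  without force, tremor, or drifting baselines would need an EMG-based
  detector.
- The GRNN is exact kernel regression: prediction cost scales with the
  number of training windows, which is fine at this study's scale but not
  for hours of data.
- Tukey homogeneous subsets assume approximately normal, homoscedastic
  per-level replicate means; the per-repeat NRMS/NMAE values are bounded
  below by 0 and mildly skewed, so borderline subset boundaries should not
  be over-interpreted.
- With few repeats the within-subset "Sig." values are coarse; grouping
  structure (membership), not the p-values, is the stable output.
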