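# Methods

This note documents the models, numerical choices and limitations behind
`imugait`. It is the package's own account of what the code computes;
every number quoted here is produced by the test suite or
`scripts/acceptance.py`, not asserted from elsewhere.

## Signal model and the synthetic cohort

The simulator generates the one signal family the event detector depends
on — shank mediolateral angular velocity — as a sum of Gaussian pulses per
stride: a positive mid-swing pulse (default 300 °/s, width σ = 5 % of the
stride) midway through the swing phase, and two negative troughs (−80 °/s
at FC, −120 °/s at IC, σ = 2 % of stride). This is a morphological model,
not a biomechanical one: it reproduces the peak/trough geometry that
defines the detection problem at a fraction of the cost of a
double-pendulum simulation, and its event times are exact by construction
(pulses are centred on the rounded event samples, so ground truth and
waveform extrema coincide within one sample). All other 40 channels are
smooth stride-locked harmonic waveforms (three harmonics, per-channel
deterministic base amplitudes and phases) plus white Gaussian noise —
enough structure for cycle features to carry group information, with no
claim to kinematic realism.

Event timing is laid down as an initial-contact ladder per side. The
contralateral IC is placed `dls_fraction` of a stride before the
ipsilateral FC; by default `dls_fraction` is derived as
`stance_fraction − 0.5`, which makes the two double-limb-support intervals
equal — the physically consistent choice for steady walking, and the reason
a symmetric zero-noise walk yields dls1 ≈ dls2.

**Stride-time asymmetry.** A constant right/left stride-time ratio r ≠ 1
makes the two sides' event ladders drift apart linearly and destroys the
alternating IC/FC interleaving within two or three strides — walking with
permanently unequal stride frequencies is not a gait. The simulator
therefore realizes r as an alternating long–short stride pattern (right
long exactly when left is short), synchronized per stride pair, such that
the *analysed* stride pair — the one starting at the second right IC,
which is where detection anchors — exhibits exactly the requested ratio.
Recovered `symmetry_stride` matches the configured ratio to < 3 % on
noise-free trials.

**Group parameters** (all config-exposed; the defaults are the study
conditions used by the tests and the acceptance script):

| group | n subjects | stride time (s) | stance fraction | asymmetry | pathology |
|---|---|---|---|---|---|
| healthy | 10 | 1.10 ± 0.03 | 0.60 ± 0.010 | 1.00 | — |
| stroke | 11 | 1.30 ± 0.05 | 0.62 ± 0.015 | 1.10 | affected side: amplitude ×0.6, noise ×3, stance +5 pp |
| other_neuro | 9 | 1.20 ± 0.04 | 0.61 ± 0.012 | 1.05 | bilateral: amplitude ×0.8, noise ×2, stance +2.5 pp |

Six trials per subject, 10 strides per trial, 148 Hz, baseline noise
2 °/s (gyroscope) and 0.02 g (accelerometer). The stroke group's affected
side is drawn once per subject and held fixed across that subject's
trials. The left shank's mediolateral axis is mirrored (negated) by
default, as physically mounted sensors often are; the detector
auto-orients per channel.

Magnitudes of the pathological effects are design choices, not measured
quantities: published descriptions of hemiparetic shank angular velocity
are qualitative ("more abrupt and noisy" on the affected side), so the
defaults were chosen once to be plausibly strong and are deliberately easy
to separate. Consequently the near-perfect classifier accuracies on
synthetic cohorts demonstrate pipeline correctness (no leakage, labels
carried through, features informative), **not** clinically attainable
accuracy.

## Filtering

All channels are filtered with a 4th-order Butterworth band-pass applied
forward–backward (`scipy.signal.sosfiltfilt`): 1–20 Hz for accelerometers,
0.25–30 Hz for gyroscopes. "4th-order bidirectional" is read as designing
a 4th-order filter and applying it twice (effective 8th-order magnitude,
zero phase); `order` is exposed for the alternative reading. Edges use
odd-symmetric extension with pad length 3·(2·order + 1); signals at least
that long are required. Zero-phase behaviour and in-band unit gain are
property-tested against an FFT oracle.

## Event detection and cycle assembly

Mid-swing: `scipy.signal.find_peaks` with the height criterion, followed
by an explicit distance-pruning pass that keeps the higher peak and breaks
ties toward the earlier index (deterministic; scipy's internal pruning is
not specified to break ties this way). Minima are detected as peaks of the
negated signal, so "minimum height 30 °/s" means troughs at or below
−30 °/s. For each mid-swing, FC is the nearest qualifying minimum before
it and IC the nearest after; a mid-swing missing either flank is flagged
invalid, never guessed. The default mid-swing height is 100 °/s (the
stricter of the two published candidates; 50 °/s is reachable through
`PeakCriteria`).

Assembly anchors at the first detected IC of the starting side (right by
default) and consumes IC/FC events strictly against the seven-event
pattern; any out-of-pattern event raises a `SequenceError` naming the
offenders. Under default timing noise roughly 3–6 % of simulated trials
fail this validation (the alternating-stride margins are a few tens of
milliseconds); such trials are excluded and logged, mirroring how unusable
trials are dropped in practice, and never imputed.

On 100 low-noise simulated trials, ≥ 95 % of IC/FC events are required to
fall within ±3 samples (≈ ±20 ms at 148 Hz) of ground truth; the measured
recovery is 100 %.

## Temporal parameters

Stance + swing = stride and stance% + swing% = 100 hold exactly by
construction; both are asserted. One published equation list labels the
swing-time formula "stance time" — the formula (IC(k+1) − FC(k)) is what
is implemented, under the name `swing_time`. The 17-feature vector is
10 durations (5 per side) + 4 percentages + 3 symmetry ratios; DLS
percentages are excluded, the only decomposition consistent with a
17-element count. The name manifest is fixed and exported.

## Cycle features

Strides are segmented half-open `[IC, IC_next)` so consecutive cycles tile
without overlap, then linearly interpolated onto a 101-point grid
(endpoints preserved). Statistics are population moments by default
(`population=False` switches to n−1 denominators); kurtosis is Fisher
(normal → 0), and a constant cycle reports kurtosis 0 with a logged note
rather than NaN. "Deviation" in the four-statistic set is implemented as
standard deviation — redundant with variance, but the 192-feature count
requires exactly four statistics. The 192 decomposition is 2 strides ×
(ipsilateral foot + shank + thigh + L5) × 6 channels × 4 statistics;
unilateral sensors are cut with the cycle of their own side, L5 with both.
Each trial contributes one row (both strides pooled into one 192-column
vector).

## Classification

ANOVA-F scores come from `sklearn.feature_selection.f_classif`, with
non-finite scores post-processed: zero within-group variance with distinct
group means → +inf (ranked first), constant features → 0. An independent
between/within mean-square oracle in the tests agrees to 1e-10 relative.
Selection keeps `max(1, floor(0.2·d))` features (38 of 192), ties broken
by ascending index. Selection is fitted on the training partition only —
the leakage-free reading — and a canary test (a feature encoding the label
on test rows only) verifies held-out accuracy cannot move.

The split is stratified 6:4 at trial level, reproducible from the seed; an
optional subject-grouped split (`subject_grouped=True`) assigns whole
subjects to one partition, since trial-level splitting lets a subject
appear on both sides. Cross-validation is stratified 5-fold with
shuffling. The default label task is the binary stroke vs
other-neurological problem; the three-group task is available via
`classes=`. Macro averaging is used for precision/recall. The MLP's
`max_iter` is capped at 300 and convergence warnings are suppressed; the
adaptive learning-rate setting is recorded although Adam governs its own
step sizes. Decision-tree and naive-Bayes hyperparameters are sklearn
defaults, pinned by the per-algorithm constructors for reproducibility.

## Problem sizes

The default cohort is (10 + 11 + 9) subjects × 6 trials = 180 trials;
event-recovery checks use 100 single/double-trial subjects at low noise;
classification tests use a 12-subject cohort. These sizes keep the full
suite and the acceptance script in the minutes range on a single CPU while
leaving every class with enough trials for stratified 5-fold
cross-validation after exclusions.

## Known limitations

- The simulator models signal morphology, not biomechanics: no spatial
  parameters (step length, velocity), no turning, no double-pendulum
  consistency between shank, thigh and foot channels.
- Synthetic separability is by construction; accuracies here say nothing
  about accuracy on real patients.
- Frequency-domain features and SVM/HMM-based methods are out of scope.
- The detector assumes the shank gyroscope mediolateral axis; it does not
  implement accelerometer-based or L5-based event detection.
- Pattern-strict assembly rejects trials rather than repairing them; with
  heavy timing noise the exclusion rate rises.
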