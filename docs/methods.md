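# Methods

## Setting and data model

The package analyses gaze recordings from a four-level puzzle task
shown on a 19-inch 1280x1024 display (~376x301 mm active area) viewed
from ~600 mm, with a remote eye tracker sampling both eyes at a
nominal 28-32 Hz and ~0.5 deg accuracy. Each session is a stream of
timestamped binocular samples (x, y, pupil diameter, validity code per
eye); performance is summarised per participant as completion time
(≤ 50 s) and correct answers (≤ 4) per level. Raw timestamps are
microseconds, fixation times milliseconds; the internal canonical
time unit is milliseconds. Gaze x/y are stored verbatim; the
recordings this dialect comes from use screen millimetres from the
top-left corner, and `ScreenGeometry.coordinate_unit` makes the unit
explicit ("px" and "normalized" are also supported). The values in
recorded files sometimes carry stray whitespace inside attributes
(e.g. `" 1.167e+12"`); the parser strips it. Printed start/end times
are coarser than the duration attribute, so the duration-consistency
check allows 5 ms of slack.

## The I-VT fixation filter

Six stages, applied in order by `run_pipeline`:

1. **Gap fill-in** (`max_gap_ms = 75`). A run of invalid samples is
   linearly interpolated, per eye and per coordinate, when the
   *missing-data duration* — the span between the flanking valid
   samples minus one nominal sampling interval — is at most 75 ms.
   We use the missing-data duration rather than the flank-to-flank
   span because at ~30 Hz the flank-to-flank span of even a
   two-sample (~60 ms) blink already exceeds 100 ms, which would make
   the 75 ms limit unable to fill any multi-sample blink. Longer runs
   are left as gaps (they reflect behaviour, e.g. looking away).
2. **Noise reduction**. A centred moving average; by default the
   narrowest symmetric window (3 samples), selectable in ms. Windows
   are truncated at gap boundaries so positions are never averaged
   across a tracking loss. The exact low-pass filter used by trackers
   is generally unspecified; a short moving average is the least
   committal choice and its effect on step edges is accounted for in
   the classification stage below.
3. **Velocity computation** (`velocity_window_ms = 20`). Both eyes are
   first combined into one cyclopean point (mean of the two when both
   valid, the single valid eye otherwise, missing when neither). Each
   sample's velocity is the visual angle between the gaze points at
   the ends of a window centred on it, divided by the window's span.
   Visual angle uses the exact two-vector (chord) form
   `2*atan(d/2D)`, not the small-angle shortcut. At ~30 Hz the 20 ms
   nominal window contains fewer than two samples, in which case it
   widens symmetrically to the nearest flanking samples — effectively
   a central difference.
4. **I-VT classification** (`velocity_threshold_deg_s = 30`, ≥ is a
   saccade). Classification is performed on the minimum of the two
   one-sided (consecutive-sample) velocities rather than on the
   centred estimate. Rationale: at this sampling rate most saccades
   start and end within a single inter-sample interval, so the
   centred window assigns a high velocity to the *stationary* samples
   flanking every saccade; they get relabelled saccadic, each
   fixation loses up to two boundary samples (more once the moving
   average has spread the step), and a genuine 150 ms fixation leaves
   a sub-100 ms run that stage 6 then deletes. A sample that is
   stationary relative to either neighbour belongs to a fixation;
   only samples moving on both sides are saccadic. Because a
   sub-sample saccade may then leave *no* saccadic sample at all,
   fixation runs are additionally split at any internal edge whose
   inter-sample velocity reaches the threshold. Run spans are
   extended toward the midpoint of the gap to the neighbouring run,
   capped at one median sampling interval (half at stream edges),
   reflecting that a sample stands for the interval around it; the
   instants alone understate every duration by a full interval.
   With these conventions, noise-free simulations recover 100 % of
   planted fixations ≥ 150 ms with boundary errors below one sample
   interval (~33 ms). Durations carry a positive bias of roughly one
   sampling interval relative to the planted events; this bias is
   common to all sessions processed with the same settings and
   cancels in group comparisons.
5. **Merging** (`merge_max_time_ms = 75`, `merge_max_angle_deg =
   0.5`, both ≤ inclusive). Adjacent fixations merge when both the
   inter-fixation interval and the angular separation of their
   centroids are within the limits; merging scans left-to-right and
   iterates to a fixed point (idempotent), the merged centroid is the
   duration-weighted mean.
6. **Duration floor** (`min_fixation_ms = 100`, ≥ kept).

All boundary conventions (≥ saccade, ≥ kept, ≤ filled/merged) are
fixed and tested; the thresholds themselves are standard I-VT practice
for remote ~30 Hz trackers.

## Heat maps and the feature vector

A fixation-count heat map accumulates, per fixation, a unit-peak
linear radial kernel (default radius 50 px) at the fixation centroid
on the pixel grid. Intensity is strictly additive; the 8-bit alpha
layer rescales intensity with saturation at a configurable level
(default: one kernel peak). "Global alpha" is defined operationally
as mean alpha coverage, `100 * sum(alpha) / (255 * n_pixels)`,
averaged over the four levels' maps.

The screen is partitioned into 3x3 quadrants A1..C3 (rows A-C top to
bottom, columns 1-3 left to right; boundary points belong to the
upper/left cell). Quadrant counts and mean durations are computed
from fixation centroids directly — not from rendered alpha mass — so
the nine counts exactly partition the total count.

The 34-entry feature vector per participant: outlier flag, global
alpha (%), total fixation count, mean/max/min fixation duration (ms),
9 quadrant counts, 9 quadrant mean durations (ms), 4 per-level times
plus total (s), 4 per-level correct counts plus total. Gaze features
pool the four levels. Per-level times must sum to the total within
0.05 s — looser than exact because published performance tables are
printed to 2 decimals and their row totals disagree with column sums
by up to 0.03 s.

## Outlier screening

Raw MAD (no 1.4826 normal-consistency factor, available as an
option); even-length medians are midpoints. A value is flagged when
`|x - median| > k * MAD` with k = 3; when MAD = 0 any off-median
value is flagged. The participant decision ORs the per-metric flags
over {global alpha, total fixation count, total correct}. Note the
zero-MAD rule is aggressive for discrete metrics in small cohorts (a
majority at one value flags everyone else), so the metric set is
configurable; at least 3 participants are required.

## Group statistics

Means and SDs use the sample convention (ddof = 1), which reproduces
the reference cohort's published summary row (total correct
11.9375, SD 2.1988 → printed 11.937 / 2.20). The weak-performer
threshold is `ceil(mean − SD)` of total correct (9.7387 → 10);
everyone strictly below it is "weak", and an equally sized "best"
group is drawn from the top of the score distribution, ties broken by
lower total time and then id.

Mann-Whitney U uses midranks, reports `U = min(U_A, U_B)`, and
satisfies `U_A + U_B = n_A n_B`. Two p conventions: the default
one-sided normal approximation with continuity correction and
tie-corrected variance (the convention under which the reference
grid's printed p values — 0.33 at U = 6, 0.056 at U = 2, 0.015 at
U = 0 for 4 vs 4 — are reproduced), and the exact permutation tail
(`method="exact"`), valid for tie-free samples and preferred at
n ≤ 10 when there are no ties. With four-versus-four groups the exact
null has only 70 arrangements, so p below 0.014 is unattainable;
these comparisons are screening, not confirmatory, statistics, and no
multiplicity correction is applied.

## Classification

Binary target: total correct ≥ threshold is "strong". Feature
selection: (a) k-best by ANOVA F-score; (b) nonzero coefficients of
L1-penalised logistic regression on standardised features (C tunes
subset size, default 0.1); (c) features whose extremely-randomised-
trees importance reaches the mean importance (retention uses ≥, so a
degenerate all-equal profile keeps everything). Classifiers: decision
tree, random forest, extra trees, AdaBoost with fixed library-default
hyperparameters. Evaluation: 100 independent stratified 60/40
train/test splits (stratification matters at n = 32 with imbalanced
classes; unstratified splits are available and re-drawn if a class is
missing from training). Everything is a pure function of the
evaluation seed. Accuracy distributions are compared with the same
Mann-Whitney machinery.

## Synthetic data

`simulate_session` renders an alternating fixation/saccade event
timeline: log-normal fixation durations (default median 200 ms,
log-SD 0.35, spanning the ~150-240 ms medians seen across real
cohorts), uniform fixation targets in the margin-inset screen with at
least 3 deg between successive targets, constant-velocity 200 deg/s
saccades (well above the 30 deg/s threshold; main-sequence kinematics
are deliberately not modelled — threshold crossing is all the filter
sees at 30 Hz), Gaussian angular noise per eye (default 0.25 deg,
half the tracker's nominal accuracy bound), and Poisson blink gaps
with durations straddling the 75 ms gap-fill limit so both fill
branches are exercised.

`simulate_cohort` draws a two-group cohort (default 32 participants,
one quarter weak): strong performers get fewer fixations decreasing
over levels (per-level Poisson means 100/30/47/40), ~0.93 per-item
success (totals near 15/16) and shorter times; weak performers many
fixations without a trend (110/99/110/141), ~0.45 success (totals
6-9) and near-cap times. Group/level fixation means sit in the ranges
observed in the reference extreme-group tables. All outputs are fully
determined by (spec, seed).

What the simulator does *not* emulate: smooth pursuit, post-saccadic
oscillations, head movement, calibration drift, pupil dynamics, and
any spatial structure of the puzzle layout (targets are uniform, so
quadrant features carry no group signal in synthetic cohorts —
separation comes from counts, durations and performance). Passing
recovery and classification tests on synthetic data therefore
demonstrates the correctness of the algorithms under the stated
generative assumptions, not field performance on real recordings.

## Problem sizes used in tests and the acceptance script

Reference-table statistics are exact desk computations on the bundled
32-row cohort and 4+4 extreme groups. Synthetic checks use 25 s
sessions at 30 Hz (four per recovery estimate, ~300 planted events),
cohorts of 8-32 participants, and 30-100 evaluation iterations —
sizes chosen to make every stochastic margin (≥ 95 % recovery,
≥ 0.95 / ≈ 0.5 accuracy) comfortably stable across seeds.
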