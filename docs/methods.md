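# Methods

`gazestate` re-implements, as a reusable pipeline, the analysis of a VR
learning-experience study in which 26 participants each completed three VR
cell-biology sessions designed to induce cognitive overload, immersion, or
distraction.  The pipeline covers the eye-tracking measurement front end
(I-VT event detection and AOI metric accumulation), the subjective/objective
statistical battery, and subject-independent cognitive-state classification.
Because the participant dataset is not public, a calibrated synthetic
generator provides study-shaped data for every stage.

## I-VT gaze-event detection

Gaze is a stream of time-stamped unit direction vectors at a nominal 120 Hz.
For each consecutive sample pair the angular difference is

    dtheta = arccos( clamp( v_i-1 . v_i , -1, 1) )      [degrees]

and the angular velocity is `v = dtheta / dt`, with `dt` always taken from
the actual timestamps (robust to dropped frames), never assumed to be
1/120 s.  Pairs with `v < 30 deg/s` are labelled fixation, pairs with
`v > 60 deg/s` saccade.  The band 30–60 deg/s is deliberately left
*unclassified*: the source thresholds define only the two outer predicates,
and inventing a third rule would add an undocumented degree of freedom.
Unclassified pairs terminate any open run, as do inter-sample gaps larger
than 3x the median interval (a blink/dropout guard; the measurement system
this emulates simply stops producing samples during signal loss).

Maximal runs of identical labels become candidate events.  Duration gates
then act as validity filters, not segmentation rules: fixations must last
100–500 ms and saccades 30–80 ms; candidates outside their window are
discarded whole, never truncated or split.  Event times are kept in seconds
internally; the CSV export reports durations in milliseconds, the unit in
which the thresholds are conventionally stated.

## AOI intersection and metric accumulation

The original system resolved "what is the learner looking at" with engine
raycasts against colliders placed on the organelles of an animal-cell model.
Here AOIs are analytic spheres (quadratic-discriminant intersection) and
axis-aligned boxes (slab method); scene units are meters in a right-handed
frame.  A ray starting inside a volume hits at distance zero — gaze from
within a collider counts as a collision.

Each validated event is attributed to the AOI hit by the majority of its
samples' rays (ties broken by the earliest hit inside the event); events
whose rays hit nothing are attributed to "none" and excluded from
accumulation.  Four cumulative metrics — fixation duration, fixation count,
saccade duration, saccade count — grow by one completed event at that
event's end time: duration by the event's full length in seconds, count
by one.  Counting once per completed event (rather than once at collision
start and once at end) matches the per-session count magnitudes of the
published descriptives.  Records are emitted on a fixed 10 Hz grid
(configurable), so a 10 s session yields ~100 records per AOI — the
bookkeeping that produces 100 time steps per session downstream.

## Synthetic data

The study reports per-state means and SDs, not raw data, so the generator
is deliberately aggregate-level; no cognitive mechanism is modelled.

**Gaze streams.**  Alternating planted fixations (dwell on an AOI center
with per-sample angular jitter drawn uniformly in [0, 0.05] deg, i.e.
velocities at most ~6 deg/s, far below the 30 deg/s gate) and saccades
(constant-rate spherical interpolation to another AOI on a ring spaced
15 deg apart, clearing the 60 deg/s gate by construction).  Planted
durations are drawn inside conservative sub-windows (fixations 150–400 ms,
saccades 42–66 ms) so that one-sample boundary quantization cannot push a
planted event outside its validity gate.  In zero-noise mode fixations are
perfectly still; the planted ground truth is retained for recovery tests.

**Metric series and questionnaires.**  For each participant x state
session, the four aggregate metrics and six scale scores (NASA-TLX, FSS,
Distractibility, and the intrinsic/extraneous/germane cognitive-load
subscales) are drawn as

    value = target_mean(state) + u_participant + residual

where `u_participant ~ N(0, (0.5 * min_state SD)^2)` is shared across the
participant's three sessions (inducing the within-subject correlation a
repeated-measures analysis needs) and the residual SD is chosen so the
marginal SD equals the published per-state SD.  The factor 0.5 on the
*smallest* per-state SD keeps every residual variance positive.  Metric
draws are clipped at zero and counts rounded; questionnaire draws are
clipped to their scale bounds (NASA-TLX anchored 0–20, FSS 1–5,
Distractibility 1–7, cognitive-load subscales 0–10; the "21-point" and
"11-point" scales are anchored at zero, a configurable choice since the
anchors are not stated in the source tables).  The clipping introduces a
small positive bias in the one heavy-tailed cell (overload saccade count,
mean 60.42, SD 47.87: ~+2.4 expected), well inside the 3-SE calibration
band at n = 26.

Each session's series is a monotone cumulative path reaching the drawn
aggregate: the drawn count of event completions is placed uniformly over
the 100-step grid and each completion adds one count and an equal share of
the drawn total duration.  The default layout — 26 participants x 3 states
x 100 steps — reproduces the study bookkeeping of 78 sessions and 7800
labelled time steps, 2600 per class.

All randomness flows from one integer seed through named sub-streams
(gaze / metrics / questionnaires) via `numpy.random.SeedSequence`.

What the generator does *not* emulate: head movement, blinks, pupil
dynamics, non-normal or skewed score distributions, state-by-participant
interaction effects, and any genuine temporal dynamics of cognition within
a session.  Passing tests therefore demonstrate pipeline correctness and
calibration to the published summary statistics — not that the models would
reach the same performance on the real recordings.

## Statistical battery

For each measure the package runs a one-way within-subject ANOVA from the
two-way (subject x state) sum-of-squares decomposition: `F = MS_state /
MS_error` with df (k-1, (k-1)(n-1)) — (2, 50) at study scale — and partial
eta squared `SS_state / (SS_state + SS_error)`.  Mauchly's W and the
Greenhouse–Geisser epsilon-hat are computed from the condition covariance
matrix on an orthonormal contrast basis; the GG-corrected p (F with both
dfs scaled by epsilon) is always reported alongside the uncorrected p,
mirroring the source analysis, which applied the correction throughout.
The implementation is cross-checked in the tests against both a
from-scratch textbook decomposition and `pingouin`.

Post hocs are Bonferroni-corrected paired t-tests (p x 3, capped at 1).
Cohen's d uses the root-mean-square pooled SD of the two conditions,

    d = |m1 - m2| / sqrt((s1^2 + s2^2) / 2),

reported as an absolute value.  This convention was frozen after verifying
that it reproduces the published post hoc effect sizes from the published
per-state means/SDs to their printed precision (two values differ by under
one unit in the last printed digit, consistent with rounding of the printed
SDs).  The 95% CI on d uses a normal approximation,
`d ± 1.96 * sqrt(1/n + d^2/(2n))`; the source's CI method is unstated and
internally inconsistent (negative CIs alongside positive d), so CIs are
reported but not validated.  Degenerate inputs (zero-variance difference
vectors, identical condition columns) return flagged results rather than
raising where the source tables imply a defined value (F = 0 for a fully
degenerate design).

Pearson correlations between metrics and scales pool all participant x
state sessions (n = 78 at study scale), with two-tailed p from the t
transform; significance is starred at 0.05/0.01/0.001.

The type-I calibration check simulates the null with iid normal scores —
sphericity then holds exactly, so it evaluates the *uncorrected* F test
against the nominal 5% level (the GG-corrected test is mildly conservative
under sphericity by construction).

## Cognitive-state classification

Per-session series are linearly resampled onto the index grid of the
longest series, then cut into sliding windows of T = 10 consecutive steps
(stride 1, so a 100-step session yields 91 windows); each window takes the
state label of its final step and never crosses a session boundary.  The
default feature set is the four metrics; a fifth timestamp channel is
available as a config option — the published layer table implies a
five-channel input while the prose names four metrics, so both are
supported, and the acceptance runs use the five-channel configuration.
(The published input length of 20 steps likewise conflicts with the prose's
window of 10; window length is a config knob defaulting to 10.)

Standardization is per channel, fitted on training windows only.
Validation for early stopping holds out 10% of *training participants*
(at least one), preserving the subject-aware principle end to end.

The classifier is a single LSTM layer (50 hidden units, tanh) -> dropout
0.2 -> batch normalization -> 3-unit softmax head, trained with
integer-label cross-entropy, Adam at 1e-3, batch size 32, up to 100 epochs,
early stopping on validation loss with best-epoch restoration.  It is
implemented directly in NumPy (forward pass, backpropagation through time,
Adam); analytic gradients are verified against central finite differences
in the test suite.  At these problem sizes (thousands of 10x5 windows) a
full LOSO run takes seconds per fold on one CPU.

Evaluation is leave-one-subject-out: one fold per participant, test = that
participant's windows, train = everyone else.  Per fold: accuracy, macro
precision/recall/F1, one-vs-rest macro-AUC from softmax scores, mean
cross-entropy, and the 3x3 confusion matrix; summaries report mean and
sample SD (ddof = 1) across folds, a per-subject accuracy listing, and
class-wise means.  Random-forest (scikit-learn) and gradient-boosted-tree
(XGBoost) baselines consume the exact same fold indices and standardized
windows, flattened.

Scaled-down evaluation sizes: the calibration and statistics checks run at
the full 26-participant scale; classification sanity checks run at 10
synthetic participants with up to 30 training epochs, and report the median
over seed replicates of the mean LOSO accuracy (subject-level variability
dominates single-draw results at this scale, exactly as the study's own
per-subject accuracies ranged from ~40% to >90%).  The label-permutation
control re-runs the identical pipeline on permuted window labels and lands
at chance (33.3% for three balanced classes).

## Known limitations

* Aggregate-level generation means the classifier's absolute accuracy on
  synthetic data is not comparable to the published 75.60%; only the
  above-chance property and the pipeline contracts are meaningful here.
* Sphere/box AOIs approximate mesh colliders; no moving AOIs.
* No blink detection, smooth pursuit, or pupil processing; the I-VT
  velocity band 30–60 deg/s is intentionally unlabelled.
* The d confidence intervals use a stated approximation and are not
  validated against the source tables.
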