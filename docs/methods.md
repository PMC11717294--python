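# Methods

This note documents the models, parameter choices and limitations behind
`chopgrip`. It states no empirical claim that the test suite or
`scripts/acceptance.py` does not itself compute.

## The measurement protocol

A trial is a 10-second recording at 30 fps of a child holding chopsticks in
the dominant hand and opening/closing them twice per second. The protocol
object (`TrialProtocol`) enforces `fps >= 2 * open_close_hz` (Nyquist) and
carries the two nuisance parameters of the simulator: per-landmark Gaussian
jitter (`noise_sd_px`, default 1.5 px) and the chopstick-detection dropout
rate (default 0.05).

## Synthetic hand kinematics

The simulator exists so that detection, geometry, summarization and
classification are each testable against known ground truth. It is a
2-D kinematic sketch, not a biomechanical model.

**Skeleton.** The 21-landmark layout (wrist + 4 joints per digit,
fingertip last) was digitized once from a traced adult hand outline and is
scaled to a configurable hand length, default 133.5 px — the cohort mean
dominant-hand length in mm at a nominal 1 px/mm. Coordinates are image
pixels, origin top-left, x right, y down.

**Motion.** Each finger flexes sinusoidally about its proximal joint,
`theta(t) = A/2 (1 - cos(2 pi f t + phi))`, with per-archetype amplitudes
and phases; the thumb opposes the fingers (phase pi). The upper chopstick
is pinched at the thumb–index fingertip midpoint and rotates with an
amplitude of 0.35 × the mean flexion of the coupled fingers (a stick swings
less than the fingers driving it; the factor also keeps the sticks from
overlapping in renders, as the real protocol keeps them open or parallel).
The lower chopstick rests on the thumb-web-to-ring-knuckle line, parallel
to the upper: static when finger IV braces it (`lower_support`), otherwise
wobbling by ±2° and ±2 px.

**Archetype parameters** (degrees of peak flexion I–V) are the package's
own design; no published kinematic amplitudes exist for these grips. They
were chosen once so that each archetype expresses its defining feature:

| archetype    | amplitudes (I–V)   | drives upper | IV braces lower | hand sway |
|--------------|--------------------|--------------|-----------------|-----------|
| four_finger  | 15, 22, 25, 3, 3   | I, II, III   | yes             | –         |
| three_finger | 12, 18, 20, 18, 6  | I, II, III   | no              | –         |
| palm         | 2 everywhere       | –            | no              | 8 px      |
| other        | 2.5 everywhere     | –            | no              | 7 px, randomized contact points |

The traditional grip's signature is a large III–IV fingertip-distance
oscillation (finger III moves, braced finger IV does not); in three-finger
prehension finger IV moves in sympathy with III, so that channel is flat.
Palm prehension is near-rigid finger geometry with whole-hand sway;
"other" is palm-like motion with the chopstick contact points offset
randomly per trial (±10 px), reflecting its definition as palm-like grips
with atypical contact.

**Ground truth.** Each sequence carries the four grip distances computed
analytically (cross-product point-to-line formula, implemented inside the
simulator independently of the feature module) on the final, noisy
coordinates, so the feature module can be checked to 1e-9.

**What the simulator does not emulate:** 3-D pose and perspective, skin
and occlusion effects on landmark estimation, correlated (non-isotropic)
landmark noise, within-child variability across trials, and chopstick
slippage events. Consequently, classifier performance on this synthetic
cohort is an upper bound and must not be read as real-video performance;
within-class kinematic variability is a free parameter here, not an
estimate of any real cohort's.

## Detection

Tape colors are segmented in HSV (hue in degrees with wrap-around support;
defaults: blue 200–260° for the upper stick, green 80–160° for the lower;
saturation ≥ 0.4, value ≥ 0.3, all configurable since lighting varies). A
3×3 morphological opening suppresses speckle. If two blobs share a color,
the largest connected component wins. The line fit is the first principal
component of the mask pixel coordinates, with endpoints at the extreme
projections; blobs with axis ratio < 1.5 trigger a low-confidence warning
because the principal direction is unstable. Masks below `min_pixels`
(default 30) are detection failures. On failure the previous pose is
carried forward unchanged for at most `max_gap = 5` frames, then the pose
is `missing` — unbounded carry-forward would fabricate data.

## Feature geometry

"Vertical distance" between a landmark and a chopstick is implemented as
the unsigned perpendicular distance to the infinite supporting line of the
fitted segment: it is invariant to camera roll and to how much of the
stick the tape covers. An image-vertical variant (|Δy| at the point's x)
is selectable for fidelity experiments; neither variant is claimed to
reproduce any particular published feature values, since the original
definition is ambiguous. Landmark indices: fingertip II = 8, first joint
of III (counted from the tip) = 11, fingertip III = 12, fingertip IV = 16.

Missing-pose frames are filled with an exact copy of the previous computed
frame (flagged `filled`); leading failures are trimmed, and failure runs
longer than `max_gap` are excluded rather than filled. Optional
normalization divides all distances and wrist-relative coordinates by the
wrist-to-fingertip-III length; the default is no normalization, because
the augmentation strategy (scaling) presumes raw-pixel features.

## Sequence summarization and CO_f1ecac

Each trial is reduced to 42 features: {CO_f1ecac, mean, SD} × 14 channels
(distances a–d and 10 fingertip coordinates). The ACF uses the biased
(divide-by-n) autocovariance normalized at lag 0, computed by FFT; the 1/e
crossing is linearly interpolated between the bracketing integer lags.
A constant series raises an error from the feature itself, but inside a
summary a zero-variance channel gets the sentinel value `length − 1`
(the maximum available lag) so summaries remain total. The tests verify
the FFT implementation against an independent direct-summation oracle and
against closed forms (alternating series: (1 − 1/e)/2 ≈ 0.316; AR(1)
φ = 0.8: ≈ −1/ln 0.8; a 2 Hz sinusoid at 30 fps: ≈ 2.85 frames).

## Classification

Pipeline order — augment raw sequences, compute features, summarize per
trial, classify at trial level — is fixed; one verdict per video is the
clinically meaningful unit. A per-frame-voting variant (tree on per-frame
rows, majority vote per trial) is available via
`cross_validate_pipeline(..., mode="frame_vote")` for comparison.

Augmentation doubles the traditional class only: one copy per traditional
trial, uniformly scaled (0.9–1.1) about the mean wrist position and
translated (±20 px per axis). Inside cross-validation, augmentation is
applied within each training fold; test folds are never augmented.

The classifier is a CART decision tree (Gini impurity, max depth 5,
minimum leaf 5, fixed random state 1234 — shallow on purpose at the
~160-trial scale). "Importance weighting" is realized as selection: fit,
rank features by impurity importance, drop those strictly below the median
importance (quantile configurable), refit. Evaluation is stratified 5-fold
CV with a fixed seed; metrics are averaged over folds with the traditional
grip as the positive class, and precision is defined as 0 (with a warning)
when no positives are predicted.

## Survey statistics

DCDQ: items 1–6 control during movement, 7–10 fine motor/handwriting,
11–15 general coordination (the standard 6/4/5 split; configurable for
translated versions); any missing item makes its subscale and the total
missing — no imputation. Grip tallies always report the four classes plus
the merged palm+others group, which is also the regression's third outcome
level (a flag can exclude "others" instead).

The multinomial logit is fitted by Newton iterations (tolerance 1e-8) with
four-finger prehension as the reference; dummy coding: boy = 1,
cohabitation yes = 1, training yes = 1, age in years, DCDQ total raw.
Missing data are handled by listwise deletion — a deliberate simplification
relative to full-information approaches, adequate at the few-nonresponse
level this design targets and documented as such. "Robust estimation" is
ordinary ML point estimates with optional sandwich (HC1) covariance, so
odds ratios are identical with and without it. Non-convergence or
non-finite estimates raise an error naming predictors that perfectly
separate an outcome level. Nagelkerke R² is Cox–Snell
`1 − exp(2(ll0 − ll1)/n)` rescaled by its maximum `1 − exp(2 ll0 / n)`.
Normality screening is the KS test with Lilliefors correction (parameters
estimated from the sample) at α = 0.05, with a log transform returned for
rejected, strictly positive variables.

## Synthetic survey cohort

`make_survey_table` draws grip classes from a multinomial logit with
user-set log-odds (non-const predictors are centered inside the linear
predictor so the default intercepts preserve the intended class mix when
slopes are nonzero). Defaults encode the study cohort's marginals as fixed
conditions: n = 165; P(age 7) = 51/165; P(boy) = 75/165; cohabitation 0.30
and prior training 0.80 (typical prevalences, not estimates); DCDQ totals
truncated-normal (51.25, 9.93) on [15, 75], distributed over items by
rounding (item-level covariance is not modeled); class mix 64:49:20:32;
maternal age truncated-normal (37.88, 6.11) on [26, 49]; maternal
taught/knows/can-use at 136, 152 and 117 per 165; two raters agreeing with
probability 0.98. Missing cells, when requested, are inserted completely
at random into the DCDQ items and household flags only.

Parameter recovery (generating ORs recovered within Monte-Carlo tolerance
at n = 5000 over 50 replicates) validates the regression machinery; it
does not validate any substantive claim about real cohorts.

## Numerical and scale choices

Problem sizes in the test suite and acceptance script — 163-trial
datasets, 20 seeds × 4 noise levels for the degradation check, 50
replicates at n = 5000 for recovery — were chosen as the smallest sizes at
which the Monte-Carlo tolerances used are comfortably above sampling
noise. Determinism: every stochastic stage takes a seed; dataset and
replicate seeds are spawned from one root generator, so identical root
seeds give bit-identical outputs. Rendering writes PNG stacks (MP4 support
is deliberately out of scope); renders are binary-masked by exact color,
so detection tests are noise-free by construction.

## Known limitations

- The simulator is 2-D and sinusoidal; it cannot express grip instability,
  slippage, or the "small III/IV movement" failure mode except through the
  noise dial.
- Classifier numbers on synthetic data do not transfer to real videos; the
  package's claim is that the machinery is correct, not that any accuracy
  level is achievable in the field.
- Listwise deletion will diverge from full-information estimates when
  missingness is heavy or informative.
- The "other" archetype is a modeling convenience (palm motion, shifted
  contacts); real "other" grips are heterogeneous.
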