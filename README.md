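# chopgrip

Objective assessment of how children hold chopsticks, from hand-landmark
video analysis to the accompanying questionnaire statistics.

## The problem

Whether a child has acquired the traditional (pincers-pinching) chopstick
grip is usually judged by eye from video, or asked of parents in surveys —
both subjective. This package implements an objective pipeline: given a
short trial in which the child rhythmically opens and closes the chopsticks
(10 s at 2 Hz), it decides from 21-point hand-landmark time series and the
chopstick positions whether the grip is **traditional** (four-finger
prehension: fingers I–III drive the upper stick while finger IV braces the
lower) or **nontraditional** (three-finger, palm, or other prehension).

It is written for researchers in motor development and occupational
therapy who want a reproducible, inspectable alternative to rater
judgment, and it ships a synthetic hand-kinematics simulator so every
stage is testable without recorded videos of children.

## The method

1. **Chopstick detection.** The sticks are wrapped in colored tape (upper
   blue, lower green). Each frame is thresholded in HSV, cleaned by a
   morphological opening, and a line segment is fitted as the principal
   axis of the mask pixels. A failed detection reuses the previous frame's
   geometry for up to 5 frames (carry-forward).
2. **Feature geometry.** Per frame, four distances (px): *a* fingertip II →
   upper stick, *b* first joint of III → upper stick, *c* fingertip III →
   lower stick, *d* fingertip III → fingertip IV, plus the raw landmark and
   stick coordinates. Stick distances are perpendicular point-to-line
   distances.
3. **Sequence summaries.** Each of 14 per-frame channels (a–d and the 10
   fingertip coordinates) is summarized by its mean, SD, and
   **CO_f1ecac** — the first lag at which the autocorrelation function
   decays below 1/e (linearly interpolated between integer lags), a
   timescale that separates rhythmically moving fingers from
   noise-dominated ones:

   r(k) = (1/n) Σₜ (xₜ − x̄)(xₜ₊ₖ − x̄) / r(0),  CO_f1ecac = min { k : r(k) < 1/e }.

4. **Classification.** Traditional trials are augmented (one scaled +
   translated copy each, doubling the class), then a depth-5 decision tree
   is fitted on the summaries; features below the median impurity
   importance are dropped and the tree refit. Evaluation is stratified
   5-fold cross-validation (accuracy, precision, recall, F1 with
   traditional as positive class).
5. **Survey statistics.** DCDQ scoring (15 items, three subscales), grip
   tallies with the palm+others merge, Fleiss' κ for inter-rater agreement,
   Lilliefors KS normality screening with optional log transform, and
   multinomial logistic regression of grip class (four-finger reference vs
   three-finger and palm+others) on age, sex, grandparent cohabitation,
   prior training and DCDQ total — odds ratios with Wald 95 % CIs, optional
   sandwich SEs, and Nagelkerke pseudo-R².

## Worked example

```python
>>> from chopgrip import make_dataset, cross_validate_pipeline, summarize_sequence
>>> ds = make_dataset(seed=1234)          # 60 traditional + 103 nontraditional trials
>>> cross_validate_pipeline(ds, seed=1234)["mean"]
{'accuracy': 1.0, 'precision': 1.0, 'recall': 1.0, 'f1': 1.0}
```

At the default landmark noise (1.5 px) the synthetic classes are cleanly
separable, so cross-validated accuracy is 1.0; it degrades monotonically as
landmark noise grows. The summaries show why: in a traditional grip the
III–IV fingertip distance oscillates at the 2 Hz protocol rate,

```python
>>> s = summarize_sequence(ds[0])         # a four_finger trial
>>> round(s.values["d_co_f1ecac"], 3), round(s.values["d_sd"], 2)
(2.721, 7.84)                              # ~2.85-frame memory of a 2 Hz rhythm, large swing
>>> s = summarize_sequence(ds[70])        # a three_finger trial: finger IV moves with III
>>> round(s.values["d_co_f1ecac"], 3), round(s.values["d_sd"], 2)
(0.794, 2.58)                              # noise-dominated channel, little swing
```

The survey side recovers known effects. Generating a cohort in which
grandparent cohabitation has odds ratio 0.15 for three-finger (vs
four-finger) prehension:

```python
>>> import math
>>> from chopgrip import make_survey_table, fit_multinomial_logit
>>> df = make_survey_table(n=5000,
...     coefficients={("cohabitation", "three_finger"): math.log(0.15)}, seed=7)
>>> fit = fit_multinomial_logit(df)
>>> round(fit.odds_ratio("cohabitation", "three_finger"), 3)
0.174                                      # one replicate; the 50-replicate mean is ~0.15
```

## Command line

```bash
chopgrip simulate --n-traditional 60 --n-nontraditional 103 --seed 1234 --out data/
chopgrip detect   --frames frames/ --out poses.csv
chopgrip features --landmarks lm.csv --poses poses.csv --out feats.csv
chopgrip train    --data data/ --out model.json
chopgrip classify --model model.json --sequence data/seq_0000.csv
chopgrip survey   --data survey.xlsx --map columns.yaml --out report/
chopgrip evaluate --data data/ --out metrics.json
```

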