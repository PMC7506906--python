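# Methods

This note documents the models, conventions and tunable parameters of
the `itug` package, and what its synthetic data can and cannot show.

## The task and the analysis chain

A subject performs five consecutive Timed Up and Go (TUG) repetitions —
stand from a chair, walk 3 m to a cone, turn about 180°, walk back, turn
and sit — with 30 s seated rests, wearing a smartphone-class IMU on the
lower back (accelerometer ±4 g, gyroscope ±500 °/s, ~100 Hz).  The
analysis predicts the Community Balance and Mobility Scale total score
(CBMS, 0–96) from features of those recordings and compares that
prediction against one built from standard clinical tests.

## Segmentation

Repetitions are found where the 1 s moving standard deviation of the
gyroscope magnitude exceeds 4 °/s; active blocks separated by less than
5 s are merged, and each block keeps 1 s of context.  Within a
repetition:

* **Turns** — the vertical-axis (yaw) angular velocity is zero-phase
  low-pass filtered at 1.5 Hz and de-biased by its median; excursions
  above 45 °/s are extended outward to the nearest crossing of
  max(5 °/s, 10 % of the excursion peak), merged when overlapping, and
  kept when the integrated angle reaches 90°.  A repetition must contain
  exactly two such turns.
* **Chair transitions** — the stand-up onset is the earliest time at
  which ML angular velocity or AP acceleration (0.1 s boxcar-smoothed;
  a boxcar has finite support, so no filter precursor leaks into the
  quiet baseline) stays above 3× its quiescent SD for ≥ 0.2 s; the sit
  end is the symmetric latest time.  Each boundary is then refined
  outward from the movement peak to the nearest crossing of
  max(1 SD, 3 % of the movement peak).  The quiescent SD comes from the
  leading (respectively trailing) 0.8 s window, which must satisfy
  absolute quiescence ceilings (6 °/s, 0.6 m/s²) — otherwise the
  recording has no usable baseline and segmentation refuses to guess.
* **Phases** — Sit-to-Walk runs from the onset to the first detected
  step; walk-out to the first turn; walk-back between the turns;
  Turn-to-Sit from the second turn's start to the sit end (the turning
  sub-interval is kept separately, since both "turning" and "total"
  Turn-to-Sit durations are reported features).  All intervals are
  half-open `[start, end)` in seconds.

All thresholds live in `SegmentationConfig` and are package defaults
typical of trunk-IMU studies; none are fitted to data.

## Feature catalogue

Exactly 78 signal features per repetition (`FEATURE_MANIFEST`), averaged
across the five repetitions with missing values ignored per feature:

* durations: Sit-to-Walk, walk (both legs), first turn, Turn-to-Sit,
  its turning sub-interval, and total;
* RMS of each acceleration axis (interval-mean-subtracted, which removes
  the gravity/posture component) and of each angular-velocity axis
  (raw), over each of the five phases;
* ranges of each angular-velocity axis per phase and of walking
  acceleration;
* normalised jerk scores of acceleration (walking — averaged over the
  two legs, since the metric needs a contiguous signal — Sit-to-Walk and
  Turn-to-Sit) and normalised angular jerk scores of the two turns;
* mean and peak yaw velocity of each turn (on a 6 Hz low-passed signal);
* step counts (walking, first turn, Turn-to-Sit, total) from band-passed
  (0.5–3 Hz) vertical acceleration peaks with ≥ 0.3 m/s² prominence and
  ≥ 0.3 s spacing;
* gait speed = 6 m / walk duration, average step length = 6 m / walking
  step count, cadence (the 6 m round trip is nominal: 2 × 3 m);
* step regularity (V and AP): unbiased autocorrelation of the
  mean-subtracted walking acceleration at the median step period, as a
  percentage of lag 0.

**Normalised jerk score.**  NJS = √( T⁵/(2A²) · ∫ j² dt ), with j the
time-derivative of acceleration (central differences) and A the
displacement excursion (max − min) of the twice-integrated
mean-subtracted acceleration.  Mean subtraction, rather than linear
detrending, is used deliberately: it removes sensor bias while leaving a
minimum-jerk pulse exact, so the metric's closed form √360 ≈ 18.97 is
reproduced and the score is invariant to time and amplitude rescaling.
The angular variant uses the integrated turn angle as A and the second
derivative of angular velocity as the angular jerk, computed with an
explicit central second difference (a repeated first-difference loses
accuracy at the interval edges, exactly where a smooth turn's jerk
peaks).  At 100 Hz the quadrature is within 2 % of the continuous value
for movements of ≥ 1 s; shorter intervals carry a few per-cent numeric
bias, which is irrelevant for their use as regression features but worth
knowing when comparing absolute values.  Jerk features are computed on
5 Hz low-passed acceleration; differentiation amplifies broadband noise,
and at the generator's default noise level unsmoothed jerk would be
noise-dominated.

## PLS regression and validation

PLS1 (NIPALS) with z-scored predictors and centred response; z-scoring
is required for VIP comparability because the catalogue mixes units
(°/s, s, steps, %).  Scores of different components are exactly
orthogonal; with as many components as the predictor rank the fit equals
ordinary least squares (both properties are tested, and coefficients are
cross-checked against an independent reference implementation).
Explained variation per component is SSY_a divided by the centred total
sum of squares; VIP uses the SSY-weighted form, so squared VIPs average
to one; VIP bands use the conventional 0.83 / 1 / 1.21 cut-offs with
boundary values assigned to the upper band.

Monte-Carlo cross-validation: each of 100 iterations randomly partitions
subjects into six near-equal sets, trains on five and tests on one.
Feature screening — keep predictors whose Pearson correlation with the
training response is significant at α = 0.05 — happens strictly inside
the loop; screening before splitting would leak the test response and
is the classic error this design avoids (a dedicated null test checks
it).  The component count is the smallest whose mean RMSEP lies within
one SD-of-the-minimum of the minimum mean (a one-SD parsimony rule; a
flat curve therefore yields one component).  The reported feature set
contains predictors selected in more than half the iterations; the final
model is refit on all subjects restricted to that set.  Explained
variation is aggregated across the iterations' training fits with
percentile 95 % confidence intervals.  Two models validated with the
same seed (hence identical partitions) are compared with a paired
Z-test on per-iteration RMSEP differences at each model's chosen
component count; pairing is valid because both models see exactly the
same folds.

Iterations in which fewer than two features survive screening are
skipped; if more than 20 % are skipped the harness aborts rather than
report an estimate based on a minority of usable partitions.

## Synthetic cohorts

A single latent mobility ability θ (community cohort centred at +1,
outpatients at −1) drives everything.  Each observed variable is
`intercept + slope·θ + noise`, clipped to its scale bounds (and rounded
for integer scales).  Because clipping shifts moments — a raw
N(15, 17.2) CBMS clipped at 0 would average ≈ 16.9 — the raw Gaussian
moments per cohort are obtained by moment-matching a *clipped* normal to
the published cohort mean/SD with a root solver; slopes and intercepts
follow from the two cohort means, and per-cohort noise SDs from the
residual variance (floored at 5 % of the scale SD).  The calibration is
deterministic, seed-independent, and reproduces the published cohort
means of CBMS, TUG time, gait speeds, SPPB, 30-s chair-stand, the
eight-level balance scale, short FES-I, age and education to within
sampling error at large n.  CBMS measurement noise is fixed at 6 points,
giving a θ–CBMS rank correlation ≈ 0.95.

Kinematic parameters (gait speed = the habitual gait-speed draw,
cadence, turn peak velocity, transition durations) are θ-linked with
cohort targets chosen from typical values for healthy seniors versus
outpatients (e.g. cadence 1.90 vs 1.65 steps/s, turn peak 160 vs
100 °/s).  The TUG *clinical column* is drawn from the calibrated latent
map like every other test; the simulated sensor-derived total duration
correlates with it but is not numerically identical.

Each repetition is assembled from movement primitives at 100 Hz:
minimum-jerk AP acceleration pulses for standing up and sitting down
(0.30 m excursion), raised-cosine ML angular-velocity pulses for the
chair transitions (50 and −40 °/s peaks), sinusoidal step oscillations
at the subject's cadence (vertical 1.2 m/s², AP 0.8 m/s², yaw 12 °/s,
pitch 15 °/s, roll 8 °/s at stride rate) with attenuated stepping inside
turns, and raised-cosine yaw pulses integrating to ±180° whose duration
follows from the subject's peak turn velocity.  Gravity rides on the
vertical accelerometer axis.  White Gaussian noise (0.15 m/s², 3 °/s)
and a 4 % log-normal repetition-to-repetition jitter on the kinematic
parameters are applied.  Because a smooth pulse has no sharp onset,
ground-truth turn boundaries are stored at the same operational
convention the detector uses (crossings of max(5 °/s, 10 % of peak) of
the noiseless pulse), the full pulse supports are stored separately, and
the walk legs are sized so the conventional walk intervals take exactly
3 m / gait speed — making "boundary error" measure detection quality
rather than an arbitrary convention mismatch.

`simulate_feature_table` bypasses signal synthesis for direct validation
tests: X = T·Pᵀ + E with exactly orthogonal unit-variance scores and
response y = T·c + e sized to a generating R² of 0.85.  The columns of P
are scaled by (3, 1, 0.35): with equal scales a single PLS covariance
direction would absorb all response signal and any table would need just
one component; decreasing scales make successive components
progressively low-variance X directions that still predict y — the
regime in which PLS genuinely needs the generating number of components,
which is what the recovery tests require.  Response weights default to
(3.5, 3.0, 2.8).

### What the synthetic data does not show

The generator's trials are far cleaner than real recordings: no
soft-tissue artifact, no device mis-orientation drift, no turning
hesitations or multi-step turns, white rather than coloured sensor
noise, strictly sinusoidal gait, and a single latent ability (plus
independent test noise) rather than multiple correlated impairment
dimensions — which is why the validated synthetic models typically
retain one component, whereas richer real cohorts can support more.
Passing tests therefore demonstrate correctness of the computational
chain and honest statistical behaviour (calibration, no leakage,
recoverable ground truth), not clinical performance on real patients.

## Problem sizes and numerical choices

Validation defaults follow the study design they emulate: 100
Monte-Carlo iterations, 6 partitions, α = 0.05, up to 10 components,
selection-frequency threshold 0.5.  The test suite exercises
segmentation on 200 noisy plus 25 noiseless trials, the screen's type-I
rate on 20 seeds × 1000 null features, leakage on a block of ten null
tables, and recovery on ten three-component tables; cohort calibration
is checked at n = 4000 per cohort.  Percentile quantiles use linear
interpolation; VIP band boundaries go to the upper band; degenerate
inputs (empty intervals, zero amplitude, zero-variance columns,
non-quiescent baselines) raise typed errors rather than propagate NaN.
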