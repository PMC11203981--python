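# Methods

## Scope and model

`ergozone` quantifies postural load as *time in zone*: the percentage of a
recording each stressed body part spends in the acceptable (green),
conditionally acceptable (orange) or unacceptable (red) posture zone defined
by a codified standard, and compares those percentages across standards.
Seven upper-body segments are modelled (neck, lower back, right/left
shoulder, right/left elbow, upper back); each anatomical degree of freedom is
one signed channel in degrees, and each movement direction of a channel is a
labelled movement axis (N1–N6, LB1–LB6, RS1–RS5, LS1–LS5, RE1–RE4, LE1–LE4).

A standard is a declarative set of threshold rules.  A rule states: for one
axis, under a work-type condition (static/dynamic/any) and support condition,
an angle region — one-sided bound, inside band, or outside band — and
optionally a movement-frequency condition (`f ≥ 2/min`, `f < 2/min`,
`f = 2/min`), and the zone it assigns (red or orange; green is the absence of
any firing rule).  Classification is per sample and per axis: red rules are
checked first, then orange.  Mirrored direction pairs are pooled into
stressed parts (e.g. `LB5/6` = lower-back rotation right/left) by worst zone.
Segments a standard does not define are reported as *not assessed* and
excluded from percentages rather than counted as green.

## Transcription of the three standards

The bundled YAML files transcribe the threshold comparison table of the
three standards cell by cell.  Conventions and interpretations, all
documented per rule in the files:

* `> x` is strict, `≥ x` inclusive; bare ranges `a–b°` are inclusive at both
  ends.  Boundary behaviour is part of the encoding, not of the engine.
* Cells marked `/` are absence-of-rule (green); segments a standard leaves
  undefined are listed as unassessed.
* The Slovak decree's static "extension without support" cell for the neck
  states no angle bound; it is encoded as any extension (angle < 0°) without
  support and flagged as an interpretation.
* Both L and S describe the upper limb by the upper arm.  Their
  flexion/extension rules sit on the shoulder elevation channel (`RS3/LS3`);
  STN EN's abduction/adduction rules sit on the horizontal-rotation channel
  (`RS4/RS5`, abduction positive), the closest channel in the wearable
  system's shoulder parameterisation.
* Captiv's paired limits written `-a/b` (e.g. horizontal rotation `-90/30`)
  bracket the acceptable band.  The engine supports this as an outside-band
  predicate; the bundled files encode each pair as two one-sided rules, one
  per movement direction, so that each labelled direction keeps its own zone
  attribution.  After stressed-part pooling the two encodings are
  equivalent.
* Neither the printed table nor the standards give numeric elbow thresholds
  (L and S treat the limb as the upper arm; the Captiv column lists shoulder
  movements only), so the elbows are marked not-assessed in all three
  bundled sets rather than encoded from invented numbers.  Qualitative cells
  ("awkward positions", "extreme positions") are likewise omitted.
* `f = 2/min` is implemented as the half-open interval `[2, 2 + q)` where
  `q` is one countable event per observation window (1/min for the default
  60 s window); exact equality is untestable on real-valued rates.

A validator reports (non-fatally) red/orange region overlaps in identical
context (legitimate, resolved by red precedence), orange one-sided bounds
exceeding the red bound on the same axis and context (monotonicity breaks —
the literal Slovak conditional cells such as "lateral flexion < 15°,
f < 2/min" produce bounded orange bands *below* the red threshold, which the
validator tolerates because the regions are bands, not one-sided bounds),
and axes carrying no rules.

## Movement frequency

The standards' `f` conditions need a repetitions-per-minute estimate per
rule threshold.  The estimator counts upward crossings of the rule's
activation bound (in the rule's movement direction) with a hysteresis of
5° — the detector re-arms only after the signal drops a full hysteresis
below the bound, so a plateau jittering around a threshold counts once —
inside a sliding 60 s window centred on each sample.  Near the recording
edges the window is *shifted*, not shrunk, so it keeps full length inside
the recording; a periodic signal therefore reports its exact steady-state
rate at every sample.  Only when the whole recording is shorter than the
window is the count rescaled to the recorded span.  (Truncating and
rescaling edge windows instead biases the rate low near the tail, where the
next cycle's crossing lies beyond the end of the recording, and breaks
exact ground-truth recovery on periodic fixtures.)  Windows are half-open
and backed off by half a sample interval so events on a window edge are
attributed deterministically.

Defaults: 20 Hz sampling, 60 s window, 5° hysteresis.  The acquisition rate
and counting algorithm of commercial systems are not published; these values
are configurable, the window matching the per-minute unit of `f` and the
hysteresis sized to suppress double counts from a few degrees of sensor
noise.  The estimate is sampling-rate invariant within one event per minute
for band-limited signals.

## Synthetic worker motion

Factory recordings of this kind are not publicly available, so the cohort is
emulated.  Each channel is `baseline + amplitude · w(t) + ε(t)` with `w` a
square, smoothed-square (raised-cosine ramps over 5% of the period) or
raised-cosine waveform of given period and duty fraction, and `ε` i.i.d.
Gaussian noise (default SD 2°).  The default task profile sketches a
standing pick–inspect–place cycle: neck flexion baseline 10° with excursions
to 35°, trunk flexion excursions to ~40°, dominant-arm elevation to ~95°,
30 s cycle period (2 picks/min — the pivot frequency of the legislative
rules), duty fractions 0.15–0.30.  These values were chosen once so that
the three standards genuinely disagree about the same motion — the
phenomenon the pipeline exists to measure — and are not fitted to any
unpublished trajectories.

The cohort generator produces 5 workers × 3 trials of 300 s by default, with
per-worker jitter (amplitude scale SD 0.08, baseline shift SD 2°, period
scale SD 0.10, duty shift SD 0.03) and anthropometrics drawn from the
reported ranges (age 23–46 y, weight 52–86 kg, height 1.68–1.85 m; BMI is
derived, not drawn).  Trials of one worker differ only in their noise
realisation.  All randomness flows from one seed through spawned
`SeedSequence` children, so cohorts are bit-reproducible.

What the generator does **not** emulate: kinematic coupling between joints
(no skeleton model or inverse kinematics), autocorrelated or
magnetic-disturbance sensor error, drift, task irregularity, or pauses.
Passing tests on synthetic data therefore demonstrate the correctness of the
classification/aggregation/statistics machinery, not the field validity of
any standard.

## Aggregation and statistics

* Time-in-zone percentages are kept at full precision; rounding to 2
  decimals happens only at reporting.
* The three trials of a worker are averaged at the percentage level by
  default ("mean of trial percentages"); classifying the sample-wise mean
  angle trajectory is available as an alternative mode, since either reading
  of "mean angle data were used" is defensible.
* The worker-level summary is the unweighted mean of Z over assessed
  stressed parts per method and zone (the source study does not state its
  aggregation rule; the mean is consistent with per-part panels feeding one
  summary row).  An instantaneous worst-zone-across-segments aggregation is
  provided behind a switch; it is stochastically redder than the mean.
* Differences are `d1 = Z_C − Z_L`, `d2 = Z_C − Z_S`, `d3 = Z_S − Z_L` per
  zone, part and worker; `d1 = d2 + d3` exactly and zone differences of a
  pair sum to zero, both verified numerically.
* The paired unit of the t-tests is the stressed part after pooling; n is
  reported per row (14 parts with the bundled standards, which leave elbows
  and upper back unassessed).  Tests are two-sided at α = 0.05.  Each
  sample is screened with Shapiro–Wilk (scipy's implementation, cross-checked
  against R's `shapiro.test` in the test suite); a normality failure flags
  the row but the test is still reported.  Constant difference vectors are
  reported as degenerate with verdict N instead of raising.  No
  multiple-testing correction is applied by default; Bonferroni and
  Benjamini–Hochberg are available.

## Published-summary reproduction

The cohort-average operation is validated against the published case-study
summary: the five printed worker rows are bundled as data, and their
column means reproduce the printed averages to 2 decimals for eight of nine
columns.  The printed legislation-red average (17.92) is not the mean of its
column (14.44) and its row sums to 103.47; a consistency check emits a
warning for exactly that cell and the reproduction explicitly excludes it.

## Numerical choices and degenerate inputs

* Zones are an `IntEnum` (green 0 < orange 1 < red 2); `NOT_ASSESSED` (−1)
  never enters severity comparisons and pools to itself only when all
  members are unassessed.
* Non-finite angles, duplicated or non-uniform timestamps, and missing
  channels raise named errors (row index, timestamp, segment/standard).
* Zero assessed samples yield a not-assessed entry, not a division error.
* Shapiro–Wilk outside 3 ≤ n ≤ 2000 and zero-variance samples raise;
  paired tests with n < 2 raise.
* Problem sizes: the default test suite and the acceptance script use 60 s
  to 300 s recordings at 20 Hz and a 120 s cohort for the full protocol —
  long enough that every frequency window is fully covered and occupancy
  quanta (one sample = 1/6000 of a 300 s recording) are far below the
  tolerances being checked.

## Known limitations

* The literal transcription of the Slovak conditional cells produces
  non-monotone severity on some axes (e.g. neck lateral flexion 10° at
  f < 2/min is orange while 20° at the same frequency matches no rule and is
  green).  This is a property of the decree's table as printed, preserved
  deliberately; the validator surfaces it rather than "fixing" it.
* Elbow and upper-back exposure cannot be scored under any bundled standard
  (no numeric thresholds exist); custom rule sets may be supplied as YAML.
* The frequency estimator's window/hysteresis are package choices, not
  published ones; conclusions that hinge on `f` near 2/min should be
  sensitivity-checked by varying them.
* Static-work support flags are per segment and per recording (optionally
  per interval), not inferred from the data.
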