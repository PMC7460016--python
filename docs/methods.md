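# Methods

## Scope and model

`motorkin` models a markerless motor screen: a depth camera tracks a
20-joint skeleton at a nominal 30 Hz while a subject performs three series
of six scripted maneuvers, and per-variable test–retest reliability is
estimated across the three series. The package has two halves: a synthetic
motion/sensor generator that replaces the camera, and the analysis chain
(segmentation → features → reliability statistics) that would run unchanged
on real recordings in the documented file format.

## Coordinate convention and data model

Camera space is right-handed, meters: +y up, +z from the camera toward the
subject, origin at the sensor. The subject stands at 2.6 m (inside the
sensor's 1.0–3.0 m working range) with the camera 0.9 m above the floor, so
a full body fits the 54.0° × 39.1° field of view; frames whose joints leave
the view volume raise a warning, not an error. Time is stored explicitly
per frame rather than derived from the rate, so dropped frames in real
recordings would not corrupt kinematics. Frame indexing is 0-based and all
spans are half-open `[start, end)`. BMI and the active/sedentary class (WHO
cut at 150 active minutes/week) are derived properties, never stored, so
their invariants cannot drift.

## The motion generator

Motion templates are minimum-jerk (5th-order polynomial) point-to-point
trajectories for reaches, steps and sit-stand cycles, and raised-cosine
amplitude-modulated oscillations for the greeting (default: both wrists,
0.35 m vertical, 2 cycles at 1.5 Hz). Smooth templates with analytically
known apices make geometric recovery exactly testable; no claim is made
that they reproduce human movement dynamics beyond that.

Design choices that matter downstream:

- **Exact between-leg angles.** The side-step and single-leg-balance poses
  place the moving ankle by rotating the stance leg's hip-center→ankle
  vector in the frontal plane, so the programmed between-leg angle is the
  rendered one to machine precision. The moving knee sits on the hip→ankle
  chord, offset forward to realize a programmed knee-flexion angle
  (default 172° during the balance hold).
- **Airborne-time compensation.** The balance hold's plateau is shortened
  by the time the min-jerk rise/lower phases spend above the 0.05 m foot
  threshold, so the total airborne time equals the programmed 10 s hold.
- **Settle pauses.** Each block is: assume the start pose (1 s min-jerk
  transition), settle 0.8 s, greet, perform the maneuver, rest 3 s. The
  pause between transition and greeting reflects how a supervised subject
  behaves and keeps pose transitions spectrally separate from the greeting
  oscillation. The protocol's three-minute rest between series carries no
  signal and is collapsed.
- **Noise model.** Sensor error is i.i.d. Gaussian per joint, frame and
  axis with σ = (6.5, 10.9, 5.7) mm in (x, y, z) — the published accuracy
  of the camera. No temporal or inter-joint correlation is modeled, because
  none is published. Postural sway is added as a slow (0.18/0.25 Hz)
  horizontal whole-body oscillation, subject-scaled around 4 mm; it is the
  only genuine signal behind the resting-sway variables, which therefore
  sit near the sensor noise floor — as they do for real markerless systems.
- **Random-effects structure.** One master seed feeds named substreams
  (subject effects, trial effects, per-recording kinematic jitter, sensor
  noise, sway phase), so any source can be zeroed independently. Subject
  effects are per-side where laterality matters (step angles N(28°, 4°),
  reach precision, arm droop, tempo, achieved balance hold, knee flexion),
  trial effects are smaller perturbations of the same parameters (e.g.
  step angle SD 1.3°), and repetition jitter is smaller still. These
  magnitudes were chosen once to land the simulated cohort in the regime a
  reliability study of healthy young adults reports: step-width and
  sit-to-stand variables with ICC ≈ 0.85–0.95, noise-floor sway variables
  poor, the rest in between.

What the generator does *not* emulate: occlusion and tracking failures,
skeleton-fitting bias, soft-tissue artifact, fatigue or learning trends
across series, and non-Gaussian heavy-tailed sensor error. Passing tests
therefore certify the analysis chain and its calibration, not performance
on real camera data.

## Segmentation

The greeting detector band-passes both wrist height traces (0.5–3 Hz,
zero-phase Butterworth of effective order 4), takes Hilbert envelopes, and
requires the *bilateral* envelope (pointwise minimum of the two) to exceed
half the minimum amplitude (default 0.2 m) for at least 0.5 s with at least
3 zero crossings of the filtered signal in each wrist — the crossing count
is what rejects monotone pose transitions, whose band-passed response is a
near-single-lobe pulse. The onset is refined by walking the supra-threshold
edge back to an 8%-of-peak floor, capped at 0.2 s so a preceding motion
hump can never be absorbed; candidates within 0.5 s merge to the earlier
one. Maneuver i spans end-of-greeting i to onset of greeting i+1, labeled
by protocol order.

Repetitions are excursions of a maneuver-specific signal (hand-to-nose
distance, between-leg angle, hip height) out of and back into a baseline
band: baseline = median of the segment's first 0.5 s, half-width = 2× the
local noise SD (robust, from first differences) floored at 5% of the peak
excursion so the noise-free case stays well-posed. Excursions must last
0.3 s and reach twice the band half-width; this separates repetitions from
noise blips by duration rather than by a global amplitude fraction, which
would mis-handle strongly lateralized subjects. Step sides are assigned by
which ankle moved laterally at the apex.

Static spans (RT, TT, and each balance hold) are cleaned of transition
frames in two steps: the longest run in which the measured joint stays
within 0.15 m of its median position, then a central-80% trim of that run.
The balance hold's angle measures further restrict to frames at ≥98% of the
plateau level (95th percentile of the airborne run), excluding rise/lower
frames from the hold-angle statistics.

## Features

Primary measures are per-frame joint-pair distances (Euclidean, m), angles
at a joint or between limb vectors (arccos of the normalized dot product,
degrees), and angular velocities (central difference over actual inter-frame
intervals, deg/s). Speeds use 3-point central differences on positions
smoothed by a 5-frame moving average (configurable off); at 30 Hz the raw
frame-to-frame differences would be dominated by the ~1 cm sensor noise.

The nose is not a tracked joint; its proxy is the HEAD joint shifted 0.10 m
along the subject's facing direction (shoulder line × vertical), which
equals "toward the camera" for a camera-facing subject but stays valid
under any yaw. "Hand" measures use the HAND joints and the arm vector is
SHOULDER→HAND, the most distal tracked pair.

Several named variables aggregate more than one physical sub-measure (e.g.
involuntary movement = resting-hand range *and* mean speed; sit-to-stand
posture = vertical hip speed *and* frontal trunk tilt). Every sub-measure
is reported individually in its physical units in `features.csv`; the
variable itself is an equal-weight z-score composite standardized against a
reference cohort (by default the input cohort) and shifted to a center of
5.0 so downstream ratio statistics (CV) keep a positive denominator.
Single-measure variables keep natural units. Composite numeric scales are
therefore cohort-relative by construction. Limb asymmetries are the mean
symmetric percent difference, 100·|L−R|/((L+R)/2), over each limb's paired
leading sub-measures (reach accuracy, reach speed, reach variability and
resting-hand range for the arms; apex foot height, airborne time and step
angle for the legs); vanishing pairs contribute 0.

All features are invariant to rigid translation and to rotation about the
vertical axis (tested), except the frontal-plane trunk tilt, which projects
onto the camera's x–y plane by definition and is translation-invariant
only.

## Reliability statistics

The one-way (subjects) decomposition gives MS_B and MS_W; ICC(1,1) =
(MS_B − MS_W)/(MS_B + (k−1)·MS_W), with the exact F-based confidence
interval from F = MS_B/MS_W and F quantiles with (n−1, n(k−1)) degrees of
freedom. The one-way form matches the one-factor ANOVA framing of the
analysis; the two-way consistency form ICC(3,1) is available behind a flag
for comparison. SEM = √MS_W — the square root of the within-subject
(intra-subject) mean square — and CV = 100·SEM divided by the grand mean of
all cells, the only reading of "SEM over the attempt average" that yields a
conventional CV; it is flagged acceptable at ≤10%.

The attempt-difference test is a one-factor repeated-measures ANOVA.
Mauchly's W is computed on the covariance of k−1 orthonormal Helmert
contrasts with Box's chi-square approximation including the second-order
correction term; the Greenhouse–Geisser ε comes from the double-centered
trial covariance, clipped to [1/(k−1), 1]. The GG-adjusted p is adopted iff
Mauchly rejects at α = 0.05; k = 2 assumes sphericity trivially. Degenerate
inputs are explicit: zero residual variance reports F = ∞ flagged
degenerate; a constant matrix has no ICC (NaN with a warning). Both the
ANOVA and the ICC are cross-checked in the test suite against pingouin as
an independent implementation and against exact rational hand computations
on a fixed integer matrix.

Effect size is Hopkins-style standardization: (mean of trial k − mean of
trial 1)/SD of trial 1, with a bias-corrected percentile bootstrap 90% CI
(2000 resamples of subjects, seeded); bands small < 0.41 ≤ moderate < 0.70
≤ large. Group comparisons take per-subject means of the attempts, then
Shapiro–Wilk per group and Levene across groups (α = 0.05) select Student's
t (with its exact CI) or the Wilcoxon–Mann–Whitney test (Hodges–Lehmann
estimate with the distribution-free normal-approximation CI); groups under
n = 3 fall back to the rank test with a warning. No multiple-testing
correction is applied across the 20 variables, mirroring per-variable
reporting conventions; listwise deletion handles missing trials with a
logged count.

## Problem sizes and determinism

The verification script and test suite use: 200 random matrices for the
ICC oracle identity, 1000 replicates per ICC level at the 29 × 3 design,
10⁴ simulations for type-I calibration, 10 subjects for geometric recovery
and the end-to-end run, and 50 subjects × 3 series for segmentation
scoring — sizes at which every Monte-Carlo margin is several standard
errors wide while a full run stays around half a minute on one CPU.
Identical configuration and seed reproduce byte-identical full-precision
JSON reports; all randomness flows from the single seed through named
substreams.

## Known limitations

- Composite variables are cohort-standardized, so their numeric scales are
  not comparable across cohorts without a fixed external reference.
- The generator's kinematics are minimum-jerk idealizations; detector and
  feature tolerances validated on them are optimistic for real data.
- The frontal trunk angle is camera-frame; a yawed subject biases it.
- Mauchly/GG inference uses the standard chi-square approximation, which is
  rough below n ≈ 10.
- The CV is undefined for variables whose mean can be zero or negative;
  the composite offset avoids this for built-in variables, and a sign
  warning is raised otherwise.
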