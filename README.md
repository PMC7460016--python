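# motorkin

Markerless motor assessment from 20-joint skeleton time series: a tested
pipeline that simulates a six-maneuver clinical motor protocol as captured by
a consumer depth camera, segments the recordings, extracts 20 motor
variables, and quantifies their test–retest reliability.

## Who this is for

Movement scientists and rehabilitation researchers who want to study —
without camera hardware — how well a markerless motor screen can separate
subjects (relative reliability) and how large its trial-to-trial measurement
error is (absolute reliability). The synthetic generator stands in for the
camera: every recording comes with exact ground truth (greeting onsets,
maneuver spans, programmed angles and durations), so each pipeline stage can
be scored against a known answer.

## The protocol and the statistics

Each subject performs three series of six maneuvers, each maneuver preceded
by a bilateral arm-flap "greeting" that marks its start:

| Maneuver | Task | Repetitions |
|---|---|---|
| RT | resting stance, arms at sides | 10 s hold |
| TT | T position, arms horizontal | 10 s hold |
| FNT | finger-to-nose, alternating arms | 5 per arm |
| SST | sideways step, maximal width | 5 per leg |
| T45 | single-leg balance, free leg abducted to 45° | 10 s hold per leg |
| CST | chair-to-stand without arm support | 5 cycles |

From the joint trajectories (20 joints × 3D at a nominal 30 Hz, with
per-axis sensor noise σ = 6.5/10.9/5.7 mm in x/y/z) the pipeline computes 20
motor variables (arm accuracy, speed, variability, involuntary movement,
step width, balance times, axial stability, sit-to-stand posture, limb
asymmetries). For each variable's *n* subjects × *k* trials matrix it
reports:

- **ICC(1,1)** — one-way random-effects intraclass correlation,
  (MS_B − MS_W) / (MS_B + (k−1) MS_W), with its exact F-based 95% CI;
  bands: &lt;0.50 poor, 0.50–0.69 moderate, 0.70–0.89 high, ≥0.90 excellent.
- **SEM** — standard error of measurement, √MS_W, in the variable's units.
- **CV** — 100·SEM / grand mean, flagged acceptable at ≤10%.
- A one-factor repeated-measures ANOVA across trials with Mauchly's
  sphericity test and the Greenhouse–Geisser ε correction, plus a
  standardized between-attempt effect size (bands 0.41 / 0.70) with a
  bias-corrected bootstrap CI.
- Active-vs-sedentary group comparisons (Student's t or
  Wilcoxon–Mann–Whitney, chosen from Shapiro–Wilk and Levene checks).

## Worked example

```bash
motorkin run --subjects 10 --series 3 --seed 7 --out demo/
```

writes `demo/recordings/*.rec.csv`, `segments.json`, `features_wide.csv` and
`report/reliability.csv`. With this seed the report begins:

```
     variable    F    p   ICC  CI_lower  CI_upper  category   SEM  CV_pct  CV_acceptable
    AccMov_LA 4.05 0.04  0.52      0.14      0.83  moderate  0.47    9.35           True
    AccMov_RA 0.74 0.49  0.79      0.53      0.94      high  0.34    6.75           True
     Veloc_LA 1.19 0.33  0.86      0.67      0.96      high  0.04    4.23           True
...
   AmpStep_RL 2.61 0.10  0.93      0.81      0.98 excellent  1.44    4.50           True
```

Reading the `AmpStep_RL` row: the right-leg step-width angle has excellent
relative reliability (ICC 0.93, CI 0.81–0.98) — subjects keep their rank
across the three series — and an absolute error of 1.44° per trial, 4.5% of
the mean step width, comfortably inside the 10% acceptability convention.
Variables dominated by the sensor noise floor (hand/head sway at rest) show
poor ICCs by construction, mirroring what markerless systems exhibit in
practice.

The same pipeline runs on any recordings in the documented file format
(JSON header + CSV body, one `<JOINT>_{x,y,z}` column triplet per joint);
the stages are also importable functions (`motorkin.simulate_cohort`,
`detect_greetings`, `extract_trial_measures`, `reliability_row`, ...).

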