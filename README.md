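# sitstandgo

Instrumented analysis of two standard clinical tests of physical
performance — the **30-second Chair Stand** (30CST: stand up and sit down
repeatedly for 30 s) and the **Timed Up and Go** (TUG: rise, walk 3 m,
turn 180°, walk back, sit) — from a single six-axis inertial sensor worn
on the lower back, for researchers in digital mobility assessment who want
a fully testable, reproducible pipeline from raw signals to compared
discrimination models.

The package covers four stages, each usable on its own:

1. **Synthetic cohorts** (`sitstandgo.synthetic`) — reproducible 100 Hz
   accelerometer + gyroscope recordings of both tests with ground-truth
   subphase annotations, per-subject latent movement parameters, and an
   LLFDI-like function score (0–100) coupled to a two-group latent with
   configurable standardized effect sizes.
2. **Segmentation** (`sitstandgo.segmentation`) — envelope-based detection
   of sit-to-stand / stand-to-sit transitions (ML angular velocity + AP
   acceleration polarity), yaw-integral-qualified turns, walking episodes
   and steps.
3. **Features** (`sitstandgo.features`) — the canonical 21 (30CST) and
   28 (TUG) movement-quality features: subphase durations and their
   variability, mean-removed RMS intensity, time-normalized jerk scores

   `NJS = sqrt(T⁵/2 · ∫ ȧ² dt)` [m],  angular `NJS = sqrt(T⁵/(2·TA²) · ∫ ω̈² dt)` [−],

   turning angle `TA = ∫ω dt`, mean/max turn velocity and step counts.
   See `docs/data_dictionary.md` for every column.
4. **Discrimination pipeline** (`sitstandgo.stats`) — median-split
   dichotomization of the function score (high vs very high functional
   status), log-transform of jerk scores + z-scoring, restricted-cubic-
   spline linearity report (3 knots at the 0.1/0.5/0.9 quantiles),
   iterative VIF pruning (< 10), univariable screening (p ≤ 0.15),
   stepwise backward logistic regression (p ≤ 0.05), Mann–Whitney AUCs
   with DeLong CIs, the paired DeLong test between models, and Harrell
   bootstrap optimism correction with full re-selection per resample.

`docs/methods.md` documents the signal model, all defaults, numerical
choices and measured calibration properties.

## Worked example

`examples/04_discrimination_models.py` generates the default 160-subject
cohort (balanced groups, ±0.5 SD effects on five latent movement
parameters), extracts features from segmented signals and fits the three
models per test. It prints:

```
cohort: 160 subjects, 80 VHFS / 80 HFS (LLFDI median 71.3)

== CST30 ==
  collinearity pruned: 10 features; screened: 6
  cst_sts_duration_sd: OR 0.44 [0.29, 0.68]
  cst_st2si_rms_gyr_ml: OR 0.69 [0.49, 0.97]
  standard     AUC 0.667 [0.586, 0.749]
  instrumented AUC 0.723 [0.644, 0.802]
  combined     AUC 0.763 [0.689, 0.838]
  DeLong standard vs instrumented: p = 0.280

== TUG ==
  collinearity pruned: 16 features; screened: 4
  tug_sit_to_walk_duration: OR 0.60 [0.43, 0.86]
  tug_tts_turning_max_velocity: OR 1.64 [1.15, 2.32]
  standard     AUC 0.608 [0.521, 0.696]
  instrumented AUC 0.673 [0.590, 0.757]
  combined     AUC 0.684 [0.601, 0.766]
  DeLong standard vs instrumented: p = 0.200
```

Reading this: odds ratios are per SD of the (log-transformed, z-scored)
feature for being in the very-high-functioning group — more variable
sit-to-stand durations (OR 0.44) and more intense stand-to-sit trunk
rotation (OR 0.69) indicate poorer function, faster turning before sitting
(OR 1.64) better function. Standard clinical and instrumented measures
discriminate similarly (DeLong p ≥ 0.2), with a small, non-significant
gain from combining them — the qualitative pattern such instrumented
studies report. The other examples (`examples/01…05`) walk through
simulation, segmentation, feature extraction and the one-call end-to-end
run individually.

A thin CLI mirrors the stages:

```bash
sitstandgo simulate --out data/ --n 20 --seed 1
sitstandgo segment --in data/S000_tug.csv --test tug --out ann.json
sitstandgo run --out results_run/ --seed 1
```

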