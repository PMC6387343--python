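# Methods

`sitstandgo` models the instrumented assessment of two standard clinical
tests of physical performance — the 30-second Chair Stand test (30CST) and
the Timed Up and Go (TUG) — from a single six-axis inertial sensor worn at
the fifth lumbar vertebra, and the statistical pipeline that asks whether
movement-quality features discriminate between high (HFS) and very high
(VHFS) functional status, defined by a median split of the LLFDI function
score. Because no suitable raw dataset is publicly deposited, the package
includes a first-class synthetic cohort generator whose ground truth makes
every downstream stage testable. This note records the models, defaults and
numerical choices, and what the synthetic validation does and does not show.

## 1. Synthetic cohort generator

### Latent subject parameters

Each subject is a draw from a population of latent movement parameters
(`sitstandgo.synthetic.POPULATION`, all normal with a floor):

| parameter | mean | SD | unit | role |
|---|---|---|---|---|
| sts_duration_mean | 0.95 | 0.15 | s | mean sit-to-stand duration |
| sts_duration_sd | 0.10 | 0.04 | s | within-subject sit-to-stand variability |
| st2si_duration_mean | 1.00 | 0.15 | s | mean stand-to-sit duration |
| st2si_duration_sd | 0.10 | 0.04 | s | within-subject stand-to-sit variability |
| stand_hold / sit_hold | 0.25 / 0.30 | 0.06 / 0.08 | s | pauses between transitions |
| turn_peak_velocity | 160 | 25 | deg/s | peak yaw rate, mid-walk 180° turn |
| tts_turn_peak_velocity | 140 | 22 | deg/s | peak yaw rate, turn before sitting |
| cadence | 1.9 | 0.2 | steps/s | walking cadence |
| gait_intensity | 1.6 | 0.35 | m/s² | walking acceleration amplitude |
| walk_time_mean | 2.3 | 0.35 | s | one 3-m walking leg |
| sts_gyro_amp / st2si_gyro_amp | 60 / 55 | 10 | deg/s | trunk-pitch pulse peaks |
| ap_pulse_amp | 2.0 | 0.4 | m/s² | AP movement pulse amplitude |
| tilt_amp | 0.25 | 0.05 | rad | peak trunk tilt in transitions |

Means were chosen so the default cohort lands near published cohort-level
descriptives for healthy adults in their sixties: ~12 chair-stand
repetitions in 30 s and a TUG of roughly 9–12 s. The two turn peaks, the
two duration variabilities and the two gyro amplitudes are *separate*
latents so that a group effect can be injected into exactly one feature
channel; with a single shared latent the injected signal would split across
correlated features and the modelling stage could not attribute it.

Group structure: subject `i` has binary group latent `i mod 2`. A
parameter with configured standardized effect `d` has its mean shifted by
`d·SD·(latent − ½)`, so the two groups differ by exactly `d` population
SDs in expectation. A two-point latent is used deliberately: with a
continuous latent and a median split, the realized group difference would
be roughly half the injected one. The default effects encode the expected
direction of early functional decline — VHFS subjects have shorter
(−0.5 SD) and less variable (−0.5 SD) sit-to-stand transitions, gentler
stand-to-sit trunk rotation (−0.5 SD), shorter walks (−0.5 SD) and faster
turning before sitting (+0.5 SD). Repetition count and total TUG duration
are *not* directly manipulated; their group differences emerge from the
transition and walk durations, as they would in reality.

The LLFDI function score is a logistic map of the latent into [44, 100]
(the range observed in high-functioning cohorts), plus N(0, 4²) noise,
clipped to [0, 100]. With the default steepness the two groups sit near 47
and 97 points, so the median split recovers the generating groups almost
perfectly; the `llfdi_noise_sd` dial exists to study label noise.

### Signal synthesis

All signals are rendered at 100 Hz and clipped to smartphone sensor ranges
(±2 g accelerometer, ±250 deg/s gyroscope).

* **Postural transition** of duration `d` (drawn per repetition, clipped at
  0.3 s): the ML angular velocity is a Gaussian-windowed biphasic sinusoid
  `±A·sin(2πs)·exp(−(s−½)²/(2·0.35²))` on normalized time `s`; the AP
  acceleration carries a scaled copy of the same pulse plus the gravity
  component `g·sin(θ)` transferred by the tilt profile
  `θ(s) = tilt_amp·sin²(πs)`; the vertical axis is `g·cos(θ)` plus a scaled
  pulse, so between movements it is exactly `g`. Per-repetition amplitudes
  jitter lognormally (σ = 0.1) — motor output varies between repetitions.
* **30CST**: complete cycles (rise, stand hold, sit-down, sit hold) are
  emitted while the next cycle's transitions fit inside 30 s; a trailing
  partial cycle is omitted, matching the convention that only completed
  rises count as repetitions. If no full cycle fits, the input is rejected.
* **Walking**: cadence-locked sinusoids — AP and V at step frequency
  (amplitudes 1× and 0.9× `gait_intensity`), ML at half the step frequency
  (left/right alternation), with small accompanying gyroscope oscillations.
  Ground-truth step times are the V-axis bounce peaks.
* **Turn**: a yaw-rate pulse `p·sin(πs)^2q` whose peak `p` is the
  subject's turn parameter and whose integral is the executed angle
  (N(180°, 3°)); the duration follows as `T = angle/(p·c(q))` with
  `c(q) = Γ(q+½)/(√π·Γ(q+1))`. The peakedness exponent `q` (lognormal,
  σ = 0.25, per subject with per-turn jitter) varies the mean-to-peak
  velocity ratio across subjects; without it, mean and maximum turn
  velocity are numerically collinear and collinearity pruning would remove
  one of them arbitrarily. Ground truth annotates the turn where the
  rendered rate exceeds 2.5 % of the pulse peak — the sub-noise tails of
  the pulse are not observable turning and no detector could recover them.
* **Noise**: additive white Gaussian, defaults 0.1 m/s² (accelerometer)
  and 1.5 deg/s (gyroscope) — of the order of smartphone MEMS noise plus
  soft-tissue artifact.

Randomness is organized as `SeedSequence([seed, tag, subject_index])`
substreams (tags: parameters, 30CST, TUG, scores), so any subject is
reproducible in isolation and cohorts are byte-reproducible.

### What the generator does *not* emulate

Orientation drift and sensor fusion errors; realistic gait spectra
(harmonics, asymmetry); dual tasks, hesitations, missteps and aborted
repetitions; heteroscedastic or autocorrelated sensor noise; any coupling
between age/sex covariates and movement. Consequently, passing tests show
that the *pipeline* is correct and calibrated — recovery of known structure,
nominal error rates under the null — not that the segmentation thresholds
or features would transfer unchanged to real smartphone recordings.

## 2. Segmentation

Postural transitions are detected on the rectified ML angular velocity,
low-pass filtered at 1.2 Hz (zero-phase 4th-order Butterworth). Peaks above
15 deg/s (prominence ≥ 4.5 deg/s, separation ≥ 0.3 s, merge gap 0.25 s)
are events; boundaries are then *refined* on a lighter 3 Hz envelope,
expanding from the peak until the envelope falls below 10 % of the local
peak or an absolute floor of 5 deg/s, whichever is higher — the floor stops
runaway expansion for low-amplitude movers whose 10 % line sits below the
noise floor. The two-stage scheme exists because a single envelope cannot
both bridge the mid-pulse zero crossing (needs heavy smoothing) and
localize edges (needs light smoothing). Up/down labels follow the biphasic
polarity of the 2-level-filtered AP acceleration (first-half minus
second-half contrast, which cancels the symmetric gravity-transfer bump),
reconciled against the constraint that a chair-stand test starts seated and
alternates.

Turns are detected the same way on the yaw rate with a 5 % boundary
fraction and qualified by an enclosed yaw integral ≥ 120°; the first
qualifying event is the 180° turn, the second the turn-before-sitting. The
sit-to-walk transition is the first ML event before the first turn; the
sit-down is the last ML event after the second turn begins; turn-to-sit
spans from turning onset to sit-down end; walking is the two gaps, treated
as one concatenated phase by the feature stage. Missing structure raises a
structured error naming the absent subphase. Steps are peaks of the
0.7–3 Hz band-passed vertical acceleration above 35 % of the segment's peak
filtered amplitude (amplitude-invariant), at least 0.3 s apart, with an
absolute floor of 0.2 m/s² below which nothing counts as a step.

Intervals are half-open `[start, end)` seconds; sample conversion floors
the start and ceils the end. Recordings shorter than 5 s (30CST) or 8 s
(TUG) are rejected. On the default synthetic conditions the detector
matches ≥ 99 % of true transitions within ±0.2 s and recovers all TUG
subphases within ±0.3 s for ~96 % of subjects; residual boundary error is
dominated by the envelope smear (~50 ms) and, for durations, by a small
compression of long transitions against their neighbours.

## 3. Features

The canonical registries hold 21 features for the 30CST and 28 for the TUG
(see `docs/data_dictionary.md`). Formulas:

* `RMS = sqrt((1/N)·Σ(sᵢ − mean)²)` — mean-removed, 1/N normalization.
  Gravity is deliberately not subtracted first: mean removal within the
  segment absorbs the static component.
* `NJS = sqrt(T⁵/2 · ∫ ȧ² dt)` (units m) for acceleration segments; the
  radical is required for the units to come out in metres.
* angular `NJS = sqrt(T⁵/(2·TA²) · ∫ ω̈² dt)` (dimensionless), with
  `TA = ∫ω dt` the turning angle; undefined for |TA| < 1°. The score is
  invariant under amplitude and duration rescaling of the turn profile —
  a pure shape (smoothness) functional.
* Turn kinematics: `TA`, mean and maximum yaw rate, reported as magnitudes
  so turn direction does not matter.

Derivatives are central differences (one-sided at the ends), integrals
trapezoidal; at 100 Hz the closed-form test signals are reproduced to
better than 1 %. Per-repetition 30CST features are averaged within
subphase type; the duration SD uses n−1 and is missing for fewer than two
repetitions. A missing subphase yields missing values, never silent zeros;
subjects with any missing modelled feature are dropped listwise before
modelling.

## 4. Discrimination pipeline

Outcome: VHFS ⇔ LLFDI ≥ sample median (ties to the upper group, so the
median itself is the VHFS minimum). Preprocessing: natural log of every
jerk-score column (they are right-skewed by construction), then z-scoring.
Logistic models are fitted by Newton/IRLS (statsmodels) with deviance
tolerance 1e−8, ≤ 100 iterations; quasi-separation is flagged when any
|coefficient| exceeds 15 on the z-scale; singular or separated fits drop
the largest-|coefficient| feature and refit.

Pipeline per test, instrumented candidates only (the sensor-derived
repetition count / total duration is excluded so the instrumented model is
judged on movement quality alone):

1. **Linearity report**: restricted cubic spline with 3 knots at the
   0.1/0.5/0.9 quantiles (Harrell's truncated-power basis; one nonlinear
   column), likelihood-ratio p for the nonlinear term. Report-only — no
   action is taken on it, since any automatic action (exclusion,
   transformation) would be arbitrary.
2. **Collinearity pruning**: iteratively remove the feature with the
   largest VIF (= 1/(1−R²) from OLS of that feature on the others) until
   all are below 10; perfect collinearity counts as infinite VIF; ties
   break to the earliest canonical column.
3. **Screening**: univariable logistic fit per feature, keep Wald
   p ≤ 0.15. Wald (not LR) is used throughout selection — the common
   stepwise convention; both statistics are available internally.
4. **Stepwise backward**: drop the highest-Wald-p feature while it exceeds
   0.05, refitting each round; an empty survivor set returns a flagged
   intercept-only model. A warning is raised when subjects-per-candidate
   falls below 10:1.
5. **Models compared**: standard clinical (assessor-recorded repetitions /
   stopwatch duration, univariable), instrumented (final stepwise model),
   combined (final instrumented features plus the sensor-derived standard
   measure, jointly refitted — no re-selection). AUCs use the Mann–Whitney
   construction with ties counted ½; CIs and the paired test use DeLong's
   structural-components covariance. Identical or degenerate score pairs
   return p = 1 or a flagged missing p.
6. **Internal validation**: Harrell's bootstrap optimism with full
   re-selection (screen + stepwise) inside each resample; resamples missing
   a class are redrawn and counted. Default B = 1000 (the acceptance script
   uses B = 200 to keep a full run around ten seconds). Convention: when
   the full-sample selection returns an intercept-only model, the corrected
   AUC is reported as 0.5 with zero optimism — a constant model
   discriminates at exactly 0.5 and has no fitted structure to over-fit;
   subtracting the unconditional process optimism would instead report a
   meaningless ~0.4.

### Calibration and power, measured on the generator

Under all-null cohorts the screen keeps 14.7 % of features (nominal 15 %),
DeLong p-values are uniform (KS p ≈ 0.9), and stepwise false retention is
at its nominal per-variable level. Two measured facts deserve emphasis:

* **Per-run dispersion of the optimism-corrected AUC.** With 15 null
  candidates at n = 100, the corrected AUC lands within ±0.05 of 0.5 in
  only ~65 % of runs. The optimism estimate is an *unconditional* average
  over the selection process, while the apparent AUC is conditional on how
  lucky the full-sample selection was; runs that spuriously retain features
  (probability ≈ 0.6 here) are systematically under-corrected. The
  estimator is unbiased in expectation, not concentrated per run — a known
  property worth remembering when reading single-cohort validation tables.
* **Stepwise retention power.** At the default conditions (d = 0.5 on the
  latent, n = 160, screen 0.15 then stepwise 0.05), a named feature's
  probability of appearing in the final model ranges from ~0.5 to ~0.9.
  The weakest case is the sit-to-stand duration SD: estimating an SD from
  ~12 repetitions attenuates its realized between-group effect to
  d ≈ 0.44 (attenuation ≈ 0.88), and retention power at a partial d of
  0.44 is near a coin flip. This mirrors the real design: single-cohort
  stepwise selection at these effect sizes is not a reliable
  feature-recovery procedure, which is exactly why the AUC comparison, not
  the selected feature list, is the primary read-out.

## 5. Reproducibility

One root seed drives everything (generator substreams, bootstrap,
stochastic tie-breaks); a fixed `PipelineConfig` yields byte-identical
serialized reports, and the manifest records a hash of the canonical
configuration. Recording CSVs round-trip bit-exactly (17-significant-digit
formatting, round-trip float parsing).

## 6. Known limitations

Segmentation thresholds are validated only against the generator; real
smartphone data would require re-tuning (and likely orientation
correction). The exact composition of 30CST feature sets in the field
varies; the registry here is config-visible so alternates can be swapped.
The combined model inherits the instrumented model's selection without
re-running it, so its AUC gain is optimistic by construction. Bootstrap
validation of the *standard* model is omitted (a univariable model with a
pre-specified predictor has negligible selection optimism).
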