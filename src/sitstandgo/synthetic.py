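"""Synthetic lumbar-IMU cohort generator.

Produces 30-s Chair Stand (30CST) and Timed Up and Go (TUG) recordings, with
ground-truth subphase annotations, for cohorts of subjects whose latent
movement parameters differ between two functional-status groups by
configurable standardized effect sizes, plus an LLFDI function score coupled
to the group latent.

Signal model (closed forms, so tests can reason about expected output)
----------------------------------------------------------------------
A postural transition of duration ``d`` occupying normalized time
``s = (t - t0)/d in [0, 1]`` is rendered as

* ML angular velocity: ``pol * A_g * sin(2*pi*s) * exp(-(s-0.5)^2/(2*0.35^2))``
  (a Gaussian-windowed biphasic sinusoid; ``pol`` is +1 for Sit-to-Stand and
  -1 for Stand-to-Sit),
* AP acceleration: the same pulse scaled by ``ap_pulse_amp`` plus the gravity
  component ``g*sin(theta)`` transferred by the trunk-tilt profile
  ``theta(s) = tilt_amp * sin(pi*s)^2``,
* V acceleration: ``g*cos(theta)`` plus a scaled copy of the movement pulse;
  outside transitions V is exactly ``g`` (so gravity handling in the feature
  stage can be tested with a known baseline).

Straight walking is a cadence-locked sinusoid: AP and V oscillate at the step
frequency (amplitude ``gait_intensity`` resp. 0.9x), ML at half the step
frequency (left/right alternation).  A 180-degree turn is a smooth yaw-rate
pulse ``p * sin(pi*t/T)^2`` whose peak ``p`` is the subject's
``turn_peak_velocity`` and whose integral is the drawn turn angle
(``T = 2*angle/p``).

Randomness: a single root seed; subject ``i`` uses substreams
``SeedSequence([seed, tag, i])`` with tag 1 (parameters), 2 (30CST), 3 (TUG),
4 (LLFDI and stopwatch), so any subject is reproducible in isolation.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .errors import ConfigurationError, DegenerateInputError
from .types import (
    GRAVITY,
    SIT_TO_STAND, STAND_TO_SIT, SIT_TO_WALK, WALK, TURN_180,
    TURN_TO_SIT, TURN_TO_SIT_TURNING,
    TEST_CST30, TEST_TUG,
    CohortSpec, SubjectParams, SubphaseAnnotation, SubphaseInterval,
    TriaxialRecording,
)

#: Population distributions of the latent subject parameters:
#: ``name -> (mean, sd, floor)``; draws are normal, clipped below at the floor.
#: Means are chosen so the default cohort lands near published cohort-level
#: descriptives for healthy adults in their sixties (about 12-13 chair-stand
#: repetitions in 30 s and a TUG around 9-11 s).
POPULATION: dict[str, tuple[float, float, float]] = {
    "sts_duration_mean": (0.95, 0.15, 0.45),
    "sts_duration_sd": (0.10, 0.04, 0.015),
    "st2si_duration_mean": (1.00, 0.15, 0.45),
    "st2si_duration_sd": (0.10, 0.04, 0.015),
    "stand_hold": (0.25, 0.06, 0.05),
    "sit_hold": (0.30, 0.08, 0.05),
    "turn_peak_velocity": (160.0, 25.0, 80.0),
    "tts_turn_peak_velocity": (140.0, 22.0, 70.0),
    "cadence": (1.90, 0.20, 1.20),
    "gait_intensity": (1.60, 0.35, 0.50),
    "walk_time_mean": (2.30, 0.35, 1.20),
    "sts_gyro_amp": (60.0, 10.0, 25.0),
    "st2si_gyro_amp": (55.0, 10.0, 25.0),
    "ap_pulse_amp": (2.00, 0.40, 0.80),
    "tilt_amp": (0.25, 0.05, 0.10),
}

#: Standardized group differences (latent 1 minus latent 0, in population-SD
#: units) that inject the qualitative signal reported for very high vs high
#: functional status: faster and less variable sit-to-stand, gentler
#: stand-to-sit trunk rotation, shorter walk, faster turning before sitting.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "sts_duration_mean": -0.5,
    "sts_duration_sd": -0.5,
    "st2si_gyro_amp": -0.5,
    "walk_time_mean": -0.5,
    "tts_turn_peak_velocity": +0.5,
}

MIN_TRANSITION_S = 0.3          # transition-duration draws are clipped below this
AMP_JITTER_SIGMA = 0.10         # lognormal sigma of per-transition amplitude jitter
PULSE_WINDOW_SIGMA = 0.35       # Gaussian window width of the transition pulse
TURN_ANGLE_SD = 3.0             # deg, jitter of the executed turn angle
TURN_SHAPE_SIGMA = 0.25         # lognormal sigma of the turn peakedness exponent
TURN_TRUTH_FRACTION = 0.025     # truth marks where the rate exceeds this x peak
STOPWATCH_SD = 0.2              # s, assessor stopwatch noise on manual TUG time
LLFDI_STEEPNESS = 6.0           # logistic link slope from latent to LLFDI
LLFDI_LO, LLFDI_HI = 44.0, 100.0

_SUBJ_PARAMS_TAG, _CST_TAG, _TUG_TAG, _SCORE_TAG = 1, 2, 3, 4


def subject_rng(seed: int, tag: int, index: int) -> np.random.Generator:
    """Deterministic substream for one subject and one purpose."""
    return np.random.default_rng(np.random.SeedSequence([seed, tag, index]))


def draw_subject_params(group_latent: float, spec: CohortSpec,
                        rng: np.random.Generator,
                        subject_id: str = "S000") -> SubjectParams:
    """Draw one subject's latent parameters.

    Each parameter is ``N(mean + d*sd*(group_latent - 0.5), sd^2)`` clipped
    below at its floor, where ``d = spec.effect_sizes.get(name, 0)``; so
    latents 1 and 0 differ in expectation by exactly ``d`` population SDs
    (floors sit several SDs below the mean and are negligible).
    """
    if not 0.0 <= group_latent <= 1.0:
        raise ConfigurationError("group_latent must lie in [0, 1]")
    values = {}
    for name, (mean, sd, floor) in POPULATION.items():
        d = spec.effect_sizes.get(name, 0.0)
        shifted = mean + d * sd * (group_latent - 0.5)
        values[name] = float(np.clip(rng.normal(shifted, sd), floor, None))
    return SubjectParams(subject_id=subject_id, **values)


def _transition_pulse(s: np.ndarray) -> np.ndarray:
    """Biphasic Gaussian-windowed sinusoid on normalized time ``s in [0,1]``."""
    return np.sin(2 * np.pi * s) * np.exp(-((s - 0.5) ** 2)
                                          / (2 * PULSE_WINDOW_SIGMA ** 2))


def _render_transition(rec: dict[str, np.ndarray], fs: float, t0: float,
                       d: float, polarity: int, gyro_amp: float,
                       params: SubjectParams, rng: np.random.Generator) -> None:
    """Add one postural transition to the signal buffers in place."""
    i0, i1 = int(round(t0 * fs)), int(round((t0 + d) * fs))
    i1 = min(i1, len(rec["acc_v"]))
    if i1 <= i0 + 1:
        return
    s = (np.arange(i0, i1) / fs - t0) / d
    jit = float(np.exp(rng.normal(0.0, AMP_JITTER_SIGMA)))
    jit_ml = float(np.exp(rng.normal(0.0, AMP_JITTER_SIGMA)))
    jit_v = float(np.exp(rng.normal(0.0, AMP_JITTER_SIGMA)))
    yaw_sign = 1.0 if rng.random() < 0.5 else -1.0
    w = _transition_pulse(s)
    bump = np.sin(np.pi * s) ** 2
    theta = params.tilt_amp * bump
    rec["gyr_ml"][i0:i1] += polarity * gyro_amp * jit * w
    rec["acc_ap"][i0:i1] += (polarity * params.ap_pulse_amp * jit * w
                             + GRAVITY * np.sin(theta))
    rec["acc_v"][i0:i1] += (GRAVITY * (np.cos(theta) - 1.0)
                            + 0.6 * params.ap_pulse_amp * jit * w)
    rec["acc_ml"][i0:i1] += 0.3 * params.ap_pulse_amp * jit_ml * bump
    rec["gyr_v"][i0:i1] += yaw_sign * 6.0 * jit_v * bump


def _render_walk(rec: dict[str, np.ndarray], fs: float, t0: float, length: float,
                 params: SubjectParams, amp_factor: float = 1.0
                 ) -> list[float]:
    """Add cadence-locked walking to the buffers; return ground-truth step times."""
    i0, i1 = int(round(t0 * fs)), int(round((t0 + length) * fs))
    i1 = min(i1, len(rec["acc_v"]))
    if i1 <= i0 + 1:
        return []
    tau = np.arange(i0, i1) / fs - t0
    phi = 2 * np.pi * params.cadence * tau
    g = amp_factor * params.gait_intensity
    rec["acc_ap"][i0:i1] += g * np.sin(phi)
    rec["acc_v"][i0:i1] += 0.9 * g * np.sin(phi)
    rec["acc_ml"][i0:i1] += 0.45 * g * np.sin(0.5 * phi)
    rec["gyr_ml"][i0:i1] += 5.0 * amp_factor * np.sin(phi)
    rec["gyr_ap"][i0:i1] += 5.0 * amp_factor * np.sin(0.5 * phi + 1.0)
    rec["gyr_v"][i0:i1] += 4.0 * amp_factor * np.sin(0.5 * phi)
    # V-axis bounce peaks at phi = pi/2 + 2*pi*k -> one "step" per cadence cycle
    steps = []
    k = 0
    while (0.25 + k) / params.cadence < length - 0.5 / fs:
        steps.append(t0 + (0.25 + k) / params.cadence)
        k += 1
    return steps


def _turn_shape_factor(q: float) -> float:
    """Mean of ``sin(pi*s)^(2q)`` over one half-period: Gamma(q+1/2)/(sqrt(pi)*Gamma(q+1))."""
    from scipy.special import gammaln
    return float(np.exp(gammaln(q + 0.5) - gammaln(q + 1.0)) / np.sqrt(np.pi))


def _render_turn(rec: dict[str, np.ndarray], fs: float, t0: float,
                 peak: float, angle: float, shape_q: float = 1.0) -> float:
    """Add a smooth yaw-rate pulse ``peak * sin(pi*s)^(2q)`` integrating to ``angle``.

    The shape exponent ``q`` sets how peaked the turn profile is (its
    mean-to-peak velocity ratio); the duration ``T = angle/(peak*c(q))``
    follows from the integral constraint, with ``c(1) = 1/2``.
    """
    T = angle / (peak * _turn_shape_factor(shape_q))
    i0, i1 = int(round(t0 * fs)), int(round((t0 + T) * fs))
    i1 = min(i1, len(rec["acc_v"]))
    s = np.clip((np.arange(i0, i1) / fs - t0) / T, 0.0, 1.0)
    rec["gyr_v"][i0:i1] += peak * np.maximum(np.sin(np.pi * s), 0.0) ** (2.0 * shape_q)
    return T


def _turn_truth_trim(shape_q: float) -> float:
    """Normalized time before which the turn rate is imperceptible.

    The rendered pulse's tails fall below ``TURN_TRUTH_FRACTION`` of its peak
    (a rate comparable to sensor noise); ground truth annotates the turn as
    the central interval where turning is actually observable.
    """
    return float(np.arcsin(TURN_TRUTH_FRACTION ** (1.0 / (2.0 * shape_q)))
                 / np.pi)


def _empty_buffers(n: int) -> dict[str, np.ndarray]:
    rec = {k: np.zeros(n) for k in
           ("acc_ap", "acc_ml", "acc_v", "gyr_ap", "gyr_ml", "gyr_v")}
    rec["acc_v"] += GRAVITY
    return rec


def _add_noise(rec: dict[str, np.ndarray], params: SubjectParams,
               rng: np.random.Generator) -> None:
    n = len(rec["acc_v"])
    if params.noise_sd_acc > 0:
        for k in ("acc_ap", "acc_ml", "acc_v"):
            rec[k] += rng.normal(0.0, params.noise_sd_acc, n)
    if params.noise_sd_gyr > 0:
        for k in ("gyr_ap", "gyr_ml", "gyr_v"):
            rec[k] += rng.normal(0.0, params.noise_sd_gyr, n)


def _finish(rec: dict[str, np.ndarray], params: SubjectParams, test_type: str,
            fs: float, truth: SubphaseAnnotation) -> TriaxialRecording:
    return TriaxialRecording(subject_id=params.subject_id, test_type=test_type,
                             fs=fs, truth=truth, **rec).clipped()


def simulate_30cst(params: SubjectParams, fs: float,
                   rng: np.random.Generator) -> TriaxialRecording:
    """Simulate one 30-s chair-stand recording.

    Cycles (Sit-to-Stand, stand hold, Stand-to-Sit, sit hold) are emitted as
    long as the next *complete* cycle's transitions fit inside 30 s; a
    trailing partial cycle is omitted.  Transition durations are drawn
    ``N(mean, sts_duration_sd^2)`` clipped at 0.3 s.  If not even one full
    cycle fits, a degenerate-input error is raised.
    """
    total = 30.0
    n = int(round(total * fs))
    rec = _empty_buffers(n)
    intervals: list[SubphaseInterval] = []
    t = 0.0
    while True:
        d_up = max(float(rng.normal(params.sts_duration_mean,
                                    params.sts_duration_sd)), MIN_TRANSITION_S)
        d_down = max(float(rng.normal(params.st2si_duration_mean,
                                      params.st2si_duration_sd)), MIN_TRANSITION_S)
        if t + d_up + params.stand_hold + d_down > total:
            break
        _render_transition(rec, fs, t, d_up, +1, params.sts_gyro_amp, params, rng)
        intervals.append(SubphaseInterval(SIT_TO_STAND, t, t + d_up))
        t += d_up + params.stand_hold
        _render_transition(rec, fs, t, d_down, -1, params.st2si_gyro_amp, params, rng)
        intervals.append(SubphaseInterval(STAND_TO_SIT, t, t + d_down))
        t += d_down + params.sit_hold
    if not intervals:
        raise DegenerateInputError(
            "not a single complete sit-stand cycle fits in 30 s")
    _add_noise(rec, params, rng)
    truth = SubphaseAnnotation(test_type=TEST_CST30, intervals=intervals)
    return _finish(rec, params, TEST_CST30, fs, truth)


def simulate_tug(params: SubjectParams, fs: float,
                 rng: np.random.Generator) -> TriaxialRecording:
    """Simulate one Timed Up and Go recording.

    Sequence: 0.5 s quiet sit, Sit-to-Walk transition, 3-m walk out,
    180-degree turn, walk back, turn-to-sit turning immediately followed by
    the sit-down transition, 1 s quiet sit.  Ground truth stores every
    subphase (walking as two episodes) plus step times.
    """
    d_stw = max(float(rng.normal(params.sts_duration_mean,
                                 params.sts_duration_sd)), MIN_TRANSITION_S)
    walk1 = max(float(rng.normal(params.walk_time_mean, 0.10)), 0.8)
    walk2 = max(float(rng.normal(params.walk_time_mean, 0.10)), 0.8)
    angle1 = float(rng.normal(180.0, TURN_ANGLE_SD))
    angle2 = float(rng.normal(180.0, TURN_ANGLE_SD))
    peak1 = params.turn_peak_velocity
    peak2 = params.tts_turn_peak_velocity
    # per-subject turn-profile peakedness (mean-to-peak velocity ratio)
    q_subj = float(np.exp(rng.normal(0.0, TURN_SHAPE_SIGMA)))
    q1 = q_subj * float(np.exp(rng.normal(0.0, 0.1)))
    q2 = q_subj * float(np.exp(rng.normal(0.0, 0.1)))
    turn1 = angle1 / (peak1 * _turn_shape_factor(q1))
    turn2 = angle2 / (peak2 * _turn_shape_factor(q2))
    d_sit = max(float(rng.normal(params.st2si_duration_mean,
                                 params.st2si_duration_sd)), MIN_TRANSITION_S)

    lead, tail = 0.5, 1.0
    total = lead + d_stw + walk1 + turn1 + walk2 + turn2 + d_sit + tail
    n = int(np.ceil(total * fs))
    rec = _empty_buffers(n)
    steps: list[float] = []

    t = lead
    _render_transition(rec, fs, t, d_stw, +1, params.sts_gyro_amp, params, rng)
    iv_stw = SubphaseInterval(SIT_TO_WALK, t, t + d_stw)
    t += d_stw
    steps += _render_walk(rec, fs, t, walk1, params)
    iv_walk1 = SubphaseInterval(WALK, t, t + walk1)
    t += walk1
    _render_turn(rec, fs, t, peak1, angle1, q1)
    steps += _render_walk(rec, fs, t, turn1, params, amp_factor=0.6)
    trim1 = _turn_truth_trim(q1) * turn1
    iv_turn = SubphaseInterval(TURN_180, t + trim1, t + turn1 - trim1)
    t += turn1
    steps += _render_walk(rec, fs, t, walk2, params)
    iv_walk2 = SubphaseInterval(WALK, t, t + walk2)
    t += walk2
    _render_turn(rec, fs, t, peak2, angle2, q2)
    steps += _render_walk(rec, fs, t, turn2, params, amp_factor=0.6)
    trim2 = _turn_truth_trim(q2) * turn2
    iv_turning = SubphaseInterval(TURN_TO_SIT_TURNING, t + trim2,
                                  t + turn2 - trim2)
    t += turn2
    _render_transition(rec, fs, t, d_sit, -1, params.st2si_gyro_amp, params, rng)
    iv_tts = SubphaseInterval(TURN_TO_SIT, iv_turning.start_s, t + d_sit)

    _add_noise(rec, params, rng)
    truth = SubphaseAnnotation(
        test_type=TEST_TUG,
        intervals=[iv_stw, iv_walk1, iv_turn, iv_walk2, iv_tts, iv_turning],
        steps=steps,
    )
    return _finish(rec, params, TEST_TUG, fs, truth)


def llfdi_from_latent(group_latent: float, noise_sd: float,
                      rng: np.random.Generator) -> float:
    """LLFDI function score: bounded logistic map of the latent plus noise.

    The noiseless map is strictly increasing from ``LLFDI_LO`` towards
    ``LLFDI_HI`` (the observed range of the score in high-functioning
    cohorts); Gaussian noise is added and the result clipped to [0, 100].
    """
    base = LLFDI_LO + (LLFDI_HI - LLFDI_LO) * float(
        expit(LLFDI_STEEPNESS * (group_latent - 0.5)))
    if noise_sd > 0:
        base += float(rng.normal(0.0, noise_sd))
    return float(np.clip(base, 0.0, 100.0))


def standard_clinical_measures(rec_cst: TriaxialRecording,
                               rec_tug: TriaxialRecording,
                               rng: np.random.Generator) -> dict[str, float]:
    """Assessor-recorded outcomes from the ground truth.

    The repetition count is the number of completed Sit-to-Stand transitions
    (assessors count these exactly); the TUG stopwatch time is the true
    Sit-to-Walk-start to Turn-to-Sit-end duration plus reaction/stopwatch
    noise.
    """
    reps = len(rec_cst.truth.by_label(SIT_TO_STAND))
    stw = rec_tug.truth.by_label(SIT_TO_WALK)[0]
    tts = rec_tug.truth.by_label(TURN_TO_SIT)[0]
    duration = tts.end_s - stw.start_s + float(rng.normal(0.0, STOPWATCH_SD))
    return {"cst30_repetitions_manual": float(reps),
            "tug_duration_manual": float(duration)}


def generate_cohort(spec: CohortSpec
                    ) -> tuple[list[tuple[TriaxialRecording, TriaxialRecording]],
                               "pandas.DataFrame"]:
    """Generate a full synthetic cohort.

    Returns one (30CST, TUG) recording pair per subject and a cohort table
    with ``subject_id, age, sex, llfdi`` plus the assessor-recorded standard
    clinical measures.  Group latents alternate 0/1 by subject index so the
    two groups are balanced for any cohort size.
    """
    import pandas as pd

    pairs = []
    rows = []
    for i in range(spec.n_subjects):
        latent = float(i % 2)
        sid = f"S{i:03d}"
        rng_p = subject_rng(spec.seed, _SUBJ_PARAMS_TAG, i)
        params = draw_subject_params(latent, spec, rng_p, subject_id=sid)
        rec_cst = simulate_30cst(params, spec.sampling_rate,
                                 subject_rng(spec.seed, _CST_TAG, i))
        rec_tug = simulate_tug(params, spec.sampling_rate,
                               subject_rng(spec.seed, _TUG_TAG, i))
        rng_s = subject_rng(spec.seed, _SCORE_TAG, i)
        llfdi = llfdi_from_latent(latent, spec.llfdi_noise_sd, rng_s)
        manual = standard_clinical_measures(rec_cst, rec_tug, rng_s)
        rows.append({
            "subject_id": sid,
            "age": float(np.clip(rng_p.normal(66.3, 2.4), 61.0, 70.0)),
            "sex": "F" if rng_p.random() < 0.544 else "M",
            "llfdi": llfdi,
            **manual,
        })
        pairs.append((rec_cst, rec_tug))
    return pairs, pd.DataFrame(rows)
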