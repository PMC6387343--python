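"""Movement-quality features of the instrumented 30CST and TUG.

Definitions (canonical registries of 21 features for the 30CST and 28 for
the TUG; ``docs/data_dictionary.md`` lists each column):

* ``RMS`` — root mean square of the mean-removed signal over a segment,
  ``sqrt(mean((s_i - mean(s))^2))`` (the 1/N-normalized standard deviation);
  a movement-intensity measure.  Mean removal also discards the static
  gravity component, so gravity is deliberately not subtracted beforehand.
* ``NJS`` — time-normalized jerk score of an acceleration segment,
  ``sqrt(T^5/2 * integral((da/dt)^2 dt))`` with duration ``T``; units m.
  Lower is smoother.
* angular ``NJS`` — for a turn's yaw rate,
  ``sqrt(T^5/(2*TA^2) * integral((d2w/dt2)^2 dt))`` where ``TA`` is the
  turning angle ``integral(w dt)``; dimensionless (invariant under amplitude
  and duration rescaling of the turn profile).
* Turn kinematics — ``TA``, mean and maximum (magnitude) yaw rate over the
  turn.

Derivatives use central differences (one-sided at segment ends), integrals
the trapezoid rule.  Per-repetition features of the 30CST are computed for
every transition and then averaged within subphase type; repetition SDs use
the n-1 denominator and are missing (NaN) for fewer than two repetitions.
Any feature whose subphase is missing is NaN, never a silent zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, UndefinedFeatureError
from .segmentation import DEFAULT_CONFIG, SegmentationConfig, count_steps
from .types import (
    SIT_TO_STAND, STAND_TO_SIT, SIT_TO_WALK, WALK, TURN_180,
    TURN_TO_SIT, TURN_TO_SIT_TURNING,
    TEST_CST30, TEST_TUG,
    SubphaseAnnotation, TriaxialRecording,
)

AXES = ("ap", "ml", "v")


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    test: str
    subphase: str
    sensor: str      # "acc", "gyr" or "none"
    axis: str        # "ap", "ml", "v" or "none"
    statistic: str   # duration, sd_duration, rms, njs, angular_njs,
                     # mean_velocity, max_velocity, steps, repetitions,
                     # total_duration


def _cst30_registry() -> list[FeatureDefinition]:
    defs = [FeatureDefinition("cst_repetitions", TEST_CST30, "Total",
                              "none", "none", "repetitions")]
    for sub, tag in ((SIT_TO_STAND, "sts"), (STAND_TO_SIT, "st2si")):
        defs.append(FeatureDefinition(f"cst_{tag}_duration_mean", TEST_CST30,
                                      sub, "none", "none", "duration"))
        defs.append(FeatureDefinition(f"cst_{tag}_duration_sd", TEST_CST30,
                                      sub, "none", "none", "sd_duration"))
        for ax in AXES:
            defs.append(FeatureDefinition(f"cst_{tag}_njs_acc_{ax}", TEST_CST30,
                                          sub, "acc", ax, "njs"))
            defs.append(FeatureDefinition(f"cst_{tag}_rms_acc_{ax}", TEST_CST30,
                                          sub, "acc", ax, "rms"))
        for ax in ("ml", "v"):
            defs.append(FeatureDefinition(f"cst_{tag}_rms_gyr_{ax}", TEST_CST30,
                                          sub, "gyr", ax, "rms"))
    return defs


def _tug_registry() -> list[FeatureDefinition]:
    defs = [FeatureDefinition("tug_total_duration", TEST_TUG, "Total",
                              "none", "none", "total_duration")]
    tags = {SIT_TO_WALK: "sit_to_walk", WALK: "walk", TURN_180: "turn180",
            TURN_TO_SIT: "turn_to_sit", TURN_TO_SIT_TURNING: "tts_turning"}
    for sub in (SIT_TO_WALK, WALK, TURN_180, TURN_TO_SIT):
        defs.append(FeatureDefinition(f"tug_{tags[sub]}_duration", TEST_TUG,
                                      sub, "none", "none", "duration"))
    for sub in (WALK, TURN_180):
        defs.append(FeatureDefinition(f"tug_{tags[sub]}_steps", TEST_TUG,
                                      sub, "acc", "v", "steps"))
    for sub in (SIT_TO_WALK, WALK, TURN_TO_SIT):
        for ax in AXES:
            defs.append(FeatureDefinition(f"tug_{tags[sub]}_rms_acc_{ax}",
                                          TEST_TUG, sub, "acc", ax, "rms"))
    for sub in (SIT_TO_WALK, TURN_TO_SIT):
        for ax in AXES:
            defs.append(FeatureDefinition(f"tug_{tags[sub]}_njs_acc_{ax}",
                                          TEST_TUG, sub, "acc", ax, "njs"))
    for sub in (TURN_180, TURN_TO_SIT_TURNING):
        tag = tags[sub]
        defs.append(FeatureDefinition(f"tug_{tag}_angular_njs", TEST_TUG,
                                      sub, "gyr", "v", "angular_njs"))
        defs.append(FeatureDefinition(f"tug_{tag}_mean_velocity", TEST_TUG,
                                      sub, "gyr", "v", "mean_velocity"))
        defs.append(FeatureDefinition(f"tug_{tag}_max_velocity", TEST_TUG,
                                      sub, "gyr", "v", "max_velocity"))
    return defs


CST30_REGISTRY: list[FeatureDefinition] = _cst30_registry()
TUG_REGISTRY: list[FeatureDefinition] = _tug_registry()
assert len(CST30_REGISTRY) == 21
assert len(TUG_REGISTRY) == 28

CST30_FEATURES = [d.name for d in CST30_REGISTRY]
TUG_FEATURES = [d.name for d in TUG_REGISTRY]
ALL_FEATURES = CST30_FEATURES + TUG_FEATURES
#: columns holding (log-normal-ish) jerk scores, log-transformed before modelling
NJS_FEATURES = [d.name for d in CST30_REGISTRY + TUG_REGISTRY
                if d.statistic in ("njs", "angular_njs")]
MANUAL_FEATURES = ["cst30_repetitions_manual", "tug_duration_manual"]


def compute_rms(segment: np.ndarray) -> float:
    """Mean-removed RMS, ``sqrt((1/N) * sum((s_i - mean)^2))``."""
    segment = np.asarray(segment, dtype=float)
    if segment.size < 2:
        raise DegenerateInputError("RMS needs at least 2 samples")
    return float(np.sqrt(np.mean((segment - segment.mean()) ** 2)))


def compute_njs(acc_segment: np.ndarray, fs: float) -> float:
    """Time-normalized jerk score ``sqrt(T^5/2 * integral(jerk^2 dt))`` [m]."""
    a = np.asarray(acc_segment, dtype=float)
    if a.size < 3:
        raise DegenerateInputError("NJS needs at least 3 samples")
    dt = 1.0 / fs
    T = (a.size - 1) * dt
    jerk = np.gradient(a, dt)
    return float(np.sqrt(T ** 5 / 2.0 * np.trapezoid(jerk ** 2, dx=dt)))


def compute_angular_njs(gyr_segment: np.ndarray, fs: float,
                        ta_tol: float = 1.0) -> float:
    """Normalized angular jerk score ``sqrt(T^5/(2*TA^2) * integral(wdd^2 dt))``.

    ``TA`` is the (signed) turning angle in degrees; magnitudes below
    ``ta_tol`` make the score undefined.
    """
    w = np.asarray(gyr_segment, dtype=float)
    if w.size < 4:
        raise DegenerateInputError("angular NJS needs at least 4 samples")
    dt = 1.0 / fs
    T = (w.size - 1) * dt
    ta = float(np.trapezoid(w, dx=dt))
    if abs(ta) < ta_tol:
        raise UndefinedFeatureError(
            f"turning angle {ta:.3g} deg too small for angular NJS")
    wdd = np.gradient(np.gradient(w, dt), dt)
    return float(np.sqrt(T ** 5 / (2.0 * ta ** 2) * np.trapezoid(wdd ** 2, dx=dt)))


def compute_turn_kinematics(gyr_v_segment: np.ndarray, fs: float
                            ) -> tuple[float, float, float]:
    """(turning angle deg, mean |velocity| deg/s, max |velocity| deg/s).

    The turning angle is the magnitude of the trapezoid integral; mean and
    max are reported as magnitudes so the values are direction-independent.
    """
    w = np.asarray(gyr_v_segment, dtype=float)
    if w.size == 0:
        raise DegenerateInputError("empty turn segment")
    ta = abs(float(np.trapezoid(w, dx=1.0 / fs)))
    return ta, abs(float(np.mean(w))), float(np.max(np.abs(w)))


def _segment_series(rec: TriaxialRecording, sensor: str, axis: str,
                    interval) -> np.ndarray:
    return rec.axis(sensor, axis)[interval.slice(rec.fs)]


def _per_repetition_mean(values: list[float]) -> float:
    vals = [v for v in values if np.isfinite(v)]
    return float(np.mean(vals)) if vals else math.nan


def extract_30cst_features(rec: TriaxialRecording, ann: SubphaseAnnotation
                           ) -> dict[str, float]:
    """One 30CST feature row (canonical 21 columns).

    With zero repetitions every feature is NaN except ``cst_repetitions = 0``;
    with a single repetition of a subphase its duration SD is NaN.
    """
    if ann.test_type != TEST_CST30:
        raise DegenerateInputError("annotation is not a CST30 annotation")
    row = {name: math.nan for name in CST30_FEATURES}
    ups = ann.by_label(SIT_TO_STAND)
    row["cst_repetitions"] = float(len(ups))
    for sub, tag in ((SIT_TO_STAND, "sts"), (STAND_TO_SIT, "st2si")):
        ivs = ann.by_label(sub)
        if not ivs:
            continue
        durations = [iv.duration for iv in ivs]
        row[f"cst_{tag}_duration_mean"] = float(np.mean(durations))
        if len(durations) >= 2:
            row[f"cst_{tag}_duration_sd"] = float(np.std(durations, ddof=1))
        for ax in AXES:
            njs, rms = [], []
            for iv in ivs:
                seg = _segment_series(rec, "acc", ax, iv)
                if seg.size >= 3:
                    njs.append(compute_njs(seg, rec.fs))
                    rms.append(compute_rms(seg))
            row[f"cst_{tag}_njs_acc_{ax}"] = _per_repetition_mean(njs)
            row[f"cst_{tag}_rms_acc_{ax}"] = _per_repetition_mean(rms)
        for ax in ("ml", "v"):
            vals = []
            for iv in ivs:
                seg = _segment_series(rec, "gyr", ax, iv)
                if seg.size >= 2:
                    vals.append(compute_rms(seg))
            row[f"cst_{tag}_rms_gyr_{ax}"] = _per_repetition_mean(vals)
    return row


def extract_tug_features(rec: TriaxialRecording, ann: SubphaseAnnotation,
                         config: SegmentationConfig = DEFAULT_CONFIG
                         ) -> dict[str, float]:
    """One TUG feature row (canonical 28 columns).

    Walking episodes are concatenated for RMS; the walk duration and step
    count sum over the episodes.  Missing subphases leave their features NaN.
    """
    if ann.test_type != TEST_TUG:
        raise DegenerateInputError("annotation is not a TUG annotation")
    row = {name: math.nan for name in TUG_FEATURES}
    if ann.is_empty:
        return row
    stw = ann.by_label(SIT_TO_WALK)
    walks = ann.by_label(WALK)
    t180 = ann.by_label(TURN_180)
    tts = ann.by_label(TURN_TO_SIT)
    turning = ann.by_label(TURN_TO_SIT_TURNING)
    if stw and tts:
        row["tug_total_duration"] = tts[0].end_s - stw[0].start_s
    if walks:
        row["tug_walk_duration"] = float(sum(iv.duration for iv in walks))
        row["tug_walk_steps"] = float(sum(count_steps(rec, iv, config)
                                          for iv in walks))
        for ax in AXES:
            seg = np.concatenate([_segment_series(rec, "acc", ax, iv)
                                  for iv in walks])
            if seg.size >= 2:
                row[f"tug_walk_rms_acc_{ax}"] = compute_rms(seg)
    for sub_ivs, tag in ((stw, "sit_to_walk"), (tts, "turn_to_sit")):
        if not sub_ivs:
            continue
        iv = sub_ivs[0]
        row[f"tug_{tag}_duration"] = iv.duration
        for ax in AXES:
            seg = _segment_series(rec, "acc", ax, iv)
            if seg.size >= 3:
                row[f"tug_{tag}_rms_acc_{ax}"] = compute_rms(seg)
                row[f"tug_{tag}_njs_acc_{ax}"] = compute_njs(seg, rec.fs)
    if t180:
        row["tug_turn180_duration"] = t180[0].duration
        row["tug_turn180_steps"] = float(count_steps(rec, t180[0], config))
    for sub_ivs, tag in ((t180, "turn180"), (turning, "tts_turning")):
        if not sub_ivs:
            continue
        seg = _segment_series(rec, "gyr", "v", sub_ivs[0])
        if seg.size < 4:
            continue
        ta, mean_v, max_v = compute_turn_kinematics(seg, rec.fs)
        row[f"tug_{tag}_mean_velocity"] = mean_v
        row[f"tug_{tag}_max_velocity"] = max_v
        try:
            row[f"tug_{tag}_angular_njs"] = compute_angular_njs(seg, rec.fs)
        except UndefinedFeatureError:
            pass
    return row


def extract_features(rec: TriaxialRecording, ann: SubphaseAnnotation,
                     config: SegmentationConfig = DEFAULT_CONFIG
                     ) -> dict[str, float]:
    """Dispatch on test type."""
    if ann.test_type == TEST_CST30:
        return extract_30cst_features(rec, ann)
    return extract_tug_features(rec, ann, config)
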