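"""Domain containers for lumbar-IMU instrumented physical-performance tests.

Conventions
-----------
* Axes are Antero-Posterior (AP), Medio-Lateral (ML) and Vertical (V), sensor at
  the fifth lumbar vertebra. Accelerations in m/s^2 (gravity included on V),
  angular velocities in deg/s.
* Sensor ranges are those of a smartphone IMU: accelerometer +/- 2 g
  (19.62 m/s^2), gyroscope +/- 250 deg/s; all synthetic output is clipped to
  these ranges.
* Subphase intervals are half-open ``[start_s, end_s)`` in seconds from the
  start of the recording; conversion to sample indices floors the start and
  ceils the end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ConfigurationError

ACC_RANGE = 2.0 * 9.81        # m/s^2, accelerometer full scale (+/- 2 g)
GYR_RANGE = 250.0             # deg/s, gyroscope full scale
GRAVITY = 9.81                # m/s^2

TEST_CST30 = "CST30"
TEST_TUG = "TUG"

# Subphase labels
SIT_TO_STAND = "SitToStand"
STAND_TO_SIT = "StandToSit"
SIT_TO_WALK = "SitToWalk"
WALK = "Walk"
TURN_180 = "Turn180"
TURN_TO_SIT = "TurnToSit"
TURN_TO_SIT_TURNING = "TurnToSitTurning"

CST30_LABELS = {SIT_TO_STAND, STAND_TO_SIT}
TUG_LABELS = {SIT_TO_WALK, WALK, TURN_180, TURN_TO_SIT, TURN_TO_SIT_TURNING}


@dataclass(frozen=True)
class SubphaseInterval:
    """A labelled half-open time interval ``[start_s, end_s)`` within a recording."""

    label: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if not (self.start_s >= 0 and self.end_s > self.start_s):
            raise ConfigurationError(
                f"invalid interval [{self.start_s}, {self.end_s}) for {self.label}"
            )

    @property
    def duration(self) -> float:
        return self.end_s - self.start_s

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_s + self.end_s)

    def slice(self, fs: float) -> slice:
        """Sample-index slice: floor the start, ceil the end."""
        return slice(int(math.floor(self.start_s * fs)),
                     int(math.ceil(self.end_s * fs)))


@dataclass
class SubphaseAnnotation:
    """Ordered subphase intervals (plus step times) for one test recording.

    For CST30, intervals alternate SitToStand / StandToSit starting with
    SitToStand.  For TUG there is exactly one SitToWalk, Turn180 and TurnToSit
    (the latter containing one TurnToSitTurning sub-interval) and one or more
    Walk episodes reported in chronological order.
    """

    test_type: str
    intervals: list[SubphaseInterval] = field(default_factory=list)
    steps: list[float] = field(default_factory=list)

    def __post_init__(self):
        if self.test_type not in (TEST_CST30, TEST_TUG):
            raise ConfigurationError(f"unknown test type {self.test_type!r}")
        self.validate()

    def validate(self) -> None:
        labels = {iv.label for iv in self.intervals}
        allowed = CST30_LABELS if self.test_type == TEST_CST30 else TUG_LABELS
        if not labels <= allowed:
            raise ConfigurationError(
                f"labels {labels - allowed} not allowed for {self.test_type}"
            )
        if self.test_type == TEST_CST30:
            seq = [iv for iv in self.intervals]
            for i, iv in enumerate(seq):
                expect = SIT_TO_STAND if i % 2 == 0 else STAND_TO_SIT
                if iv.label != expect:
                    raise ConfigurationError(
                        "CST30 intervals must alternate SitToStand/StandToSit "
                        f"starting with SitToStand (position {i}: {iv.label})"
                    )
            self._check_no_overlap(seq)
        else:
            main = [iv for iv in self.intervals
                    if iv.label != TURN_TO_SIT_TURNING]
            for lab in (SIT_TO_WALK, TURN_180, TURN_TO_SIT):
                n = sum(iv.label == lab for iv in self.intervals)
                if self.intervals and n != 1:
                    raise ConfigurationError(f"TUG needs exactly one {lab}, got {n}")
            if self.intervals:
                stw = self.by_label(SIT_TO_WALK)[0]
                t180 = self.by_label(TURN_180)[0]
                tts = self.by_label(TURN_TO_SIT)[0]
                if not (stw.start_s < t180.start_s < tts.start_s):
                    raise ConfigurationError("TUG subphases out of order")
                turning = self.by_label(TURN_TO_SIT_TURNING)
                if len(turning) != 1:
                    raise ConfigurationError("TUG needs exactly one TurnToSitTurning")
                tg = turning[0]
                if not (tts.start_s - 1e-9 <= tg.start_s and
                        tg.end_s <= tts.end_s + 1e-9):
                    raise ConfigurationError(
                        "TurnToSitTurning must lie within TurnToSit")
                self._check_no_overlap(sorted(main, key=lambda iv: iv.start_s))

    @staticmethod
    def _check_no_overlap(seq: list[SubphaseInterval]) -> None:
        for a, b in zip(seq, seq[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ConfigurationError(
                    f"overlapping intervals: {a.label}@{a.end_s} / {b.label}@{b.start_s}"
                )

    def by_label(self, label: str) -> list[SubphaseInterval]:
        return [iv for iv in self.intervals if iv.label == label]

    @property
    def is_empty(self) -> bool:
        return not self.intervals


@dataclass
class TriaxialRecording:
    """One test's synchronized 6-axis IMU time series.

    ``truth`` optionally holds the generator's ground-truth annotation.
    """

    subject_id: str
    test_type: str
    fs: float
    acc_ap: np.ndarray
    acc_ml: np.ndarray
    acc_v: np.ndarray
    gyr_ap: np.ndarray
    gyr_ml: np.ndarray
    gyr_v: np.ndarray
    truth: Optional[SubphaseAnnotation] = None

    def __post_init__(self):
        if self.fs <= 0:
            raise ConfigurationError("sampling rate must be positive")
        n = len(self.acc_ap)
        for name in ("acc_ml", "acc_v", "gyr_ap", "gyr_ml", "gyr_v"):
            if len(getattr(self, name)) != n:
                raise ConfigurationError("all six series must have equal length")
        if n < 2:
            raise ConfigurationError("recording must contain at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.acc_ap)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def axis(self, sensor: str, axis: str) -> np.ndarray:
        """Return one series, e.g. ``axis('acc', 'ap')``."""
        return getattr(self, f"{sensor}_{axis.lower()}")

    def clipped(self) -> "TriaxialRecording":
        """Return a copy with every sample clipped to the sensor ranges."""
        return TriaxialRecording(
            subject_id=self.subject_id, test_type=self.test_type, fs=self.fs,
            acc_ap=np.clip(self.acc_ap, -ACC_RANGE, ACC_RANGE),
            acc_ml=np.clip(self.acc_ml, -ACC_RANGE, ACC_RANGE),
            acc_v=np.clip(self.acc_v, -ACC_RANGE, ACC_RANGE),
            gyr_ap=np.clip(self.gyr_ap, -GYR_RANGE, GYR_RANGE),
            gyr_ml=np.clip(self.gyr_ml, -GYR_RANGE, GYR_RANGE),
            gyr_v=np.clip(self.gyr_v, -GYR_RANGE, GYR_RANGE),
            truth=self.truth,
        )


@dataclass(frozen=True)
class SubjectParams:
    """Latent per-subject movement parameters behind one synthetic subject.

    These are the "truth" a recording is rendered from; group differences are
    injected by shifting their means (see :mod:`sitstandgo.synthetic`).
    """

    subject_id: str
    sts_duration_mean: float      # s, mean Sit-to-Stand transition duration
    sts_duration_sd: float        # s, within-subject Sit-to-Stand variability
    st2si_duration_mean: float    # s, mean Stand-to-Sit duration
    st2si_duration_sd: float      # s, within-subject Stand-to-Sit variability
    stand_hold: float             # s, pause standing between transitions
    sit_hold: float               # s, pause seated between cycles
    turn_peak_velocity: float     # deg/s, peak yaw rate of the mid-walk 180 turn
    tts_turn_peak_velocity: float  # deg/s, peak yaw rate of the turn before sitting
    cadence: float                # steps/s while walking
    gait_intensity: float         # m/s^2, amplitude of walking accelerations
    walk_time_mean: float         # s, time for one 3-m straight-walk leg
    sts_gyro_amp: float           # deg/s, ML trunk-pitch pulse peak, sit-to-stand
    st2si_gyro_amp: float         # deg/s, ML trunk-pitch pulse peak, stand-to-sit
    ap_pulse_amp: float           # m/s^2, AP movement pulse amplitude in transitions
    tilt_amp: float               # rad, peak trunk tilt during transitions
    noise_sd_acc: float = 0.1     # m/s^2, additive white accelerometer noise
    noise_sd_gyr: float = 1.5     # deg/s, additive white gyroscope noise

    def __post_init__(self):
        positive = ("sts_duration_mean", "st2si_duration_mean",
                    "turn_peak_velocity", "tts_turn_peak_velocity",
                    "cadence", "walk_time_mean",
                    "sts_gyro_amp", "st2si_gyro_amp", "ap_pulse_amp", "tilt_amp")
        nonneg = ("sts_duration_sd", "st2si_duration_sd", "stand_hold",
                  "sit_hold", "gait_intensity", "noise_sd_acc", "noise_sd_gyr")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        cycle = (self.sts_duration_mean + self.stand_hold
                 + self.st2si_duration_mean + self.sit_hold)
        if cycle > 30.0:
            raise ConfigurationError(
                f"full 30CST cycle ({cycle:.1f} s) exceeds the 30 s test")


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort.

    ``effect_sizes`` maps a :class:`SubjectParams` field name to a standardized
    group difference d: subjects with group latent 1 (very high functional
    status) have that parameter's population mean shifted by ``+d`` SDs
    relative to latent 0.
    """

    n_subjects: int = 160
    effect_sizes: dict = field(default_factory=dict)
    llfdi_noise_sd: float = 4.0   # points on the 0-100 LLFDI scale
    seed: int = 0
    sampling_rate: float = 100.0  # Hz

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigurationError("n_subjects must be >= 2")
        if self.sampling_rate <= 0:
            raise ConfigurationError("sampling_rate must be > 0")
        if self.llfdi_noise_sd < 0:
            raise ConfigurationError("llfdi_noise_sd must be >= 0")
        from .synthetic import POPULATION  # deferred: avoid cycle at import
        unknown = set(self.effect_sizes) - set(POPULATION)
        if unknown:
            raise ConfigurationError(f"unknown effect_sizes keys: {sorted(unknown)}")


@dataclass
class LogisticFit:
    """A fitted (possibly intercept-only) logistic regression."""

    features: list[str]
    coefficients: np.ndarray          # includes intercept first
    standard_errors: np.ndarray
    pvalues: np.ndarray               # Wald, two-sided
    probabilities: np.ndarray         # per-subject fitted P(VHFS)
    converged: bool
    llf: float
    flags: list[str] = field(default_factory=list)

    @property
    def odds_ratios(self) -> dict[str, tuple[float, float, float]]:
        """Per-feature OR with Wald 95% CI as ``{name: (or, lo, hi)}``."""
        out = {}
        for i, name in enumerate(self.features, start=1):
            b, se = self.coefficients[i], self.standard_errors[i]
            out[name] = (float(np.exp(b)),
                         float(np.exp(b - 1.959963984540054 * se)),
                         float(np.exp(b + 1.959963984540054 * se)))
        return out

    @property
    def is_intercept_only(self) -> bool:
        return not self.features


@dataclass
class RocComparison:
    """Paired comparison of two models' AUCs on the same subjects."""

    auc_a: float
    auc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    delong_z: Optional[float]
    delong_p: Optional[float]
    flags: list[str] = field(default_factory=list)


@dataclass
class VifReport:
    """Trace of iterative variance-inflation-factor pruning."""

    removed: list[tuple[str, float]]   # (feature, VIF at removal time)
    surviving: list[str]
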