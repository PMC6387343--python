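"""Feature formulas against closed-form oracles; extraction against truth."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sitstandgo import (
    CST30_FEATURES, CST30_REGISTRY, TUG_FEATURES, TUG_REGISTRY,
    compute_angular_njs, compute_njs, compute_rms, compute_turn_kinematics,
    detect_transitions_30cst, extract_30cst_features, extract_tug_features,
    segment_tug, simulate_30cst,
)
from sitstandgo.errors import DegenerateInputError, UndefinedFeatureError
from sitstandgo.synthetic import subject_rng
from sitstandgo.types import SubphaseAnnotation

FS = 100.0


class TestComputeRms:
    def test_hand_evaluated_example(self):
        # {1,2,3}: mean 2, mean squared deviation 2/3
        assert compute_rms([1.0, 2.0, 3.0]) == pytest.approx(math.sqrt(2 / 3))

    def test_constant_segment_is_zero(self):
        assert compute_rms(np.full(50, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_full_period_sine(self):
        t = np.arange(100) / FS
        a = 2.5
        assert compute_rms(a * np.sin(2 * np.pi * t)) == pytest.approx(
            a / math.sqrt(2), rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(DegenerateInputError):
            compute_rms([1.0])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=200),
           st.floats(-10, 10))
    def test_matches_two_pass_oracle_and_is_shift_invariant(self, xs, shift):
        x = np.array(xs)
        m = sum(xs) / len(xs)
        oracle = math.sqrt(sum((v - m) ** 2 for v in xs) / len(xs))
        assert compute_rms(x) == pytest.approx(oracle, abs=1e-9)
        assert compute_rms(x + shift) == pytest.approx(oracle, abs=1e-7)


class TestComputeNjs:
    def test_linear_ramp_closed_form(self):
        # a(t) = t on [0,1]: jerk = 1, NJS = sqrt(1/2)
        t = np.linspace(0.0, 1.0, 101)
        assert compute_njs(t, FS) == pytest.approx(1 / math.sqrt(2), rel=1e-3)

    def test_constant_acceleration_is_zero(self):
        assert compute_njs(np.full(100, 9.81), FS) == 0.0

    def test_amplitude_homogeneity(self):
        rng = np.random.default_rng(3)
        a = np.cumsum(rng.normal(size=200)) / 10
        c = 3.7
        assert compute_njs(c * a, FS) == pytest.approx(
            c * compute_njs(a, FS), rel=1e-12)

    def test_convergence_with_sampling_rate(self):
        # smooth pulse: relative error <= 1% at 100 Hz, <= 0.01% at 10 kHz
        def njs_of(fs):
            t = np.linspace(0.0, 1.0, int(fs) + 1)
            return compute_njs(np.sin(np.pi * t) ** 2, fs)
        exact = njs_of(200000)
        assert abs(njs_of(100) - exact) / exact < 0.01
        assert abs(njs_of(10000) - exact) / exact < 1e-4


class TestComputeAngularNjs:
    @staticmethod
    def _turn(peak, T, fs=FS, q=1.0):
        t = np.linspace(0.0, T, int(round(T * fs)) + 1)
        return peak * np.sin(np.pi * t / T) ** (2 * q)

    def test_amplitude_and_duration_invariance(self):
        base = compute_angular_njs(self._turn(100.0, 2.0), FS)
        amp = compute_angular_njs(self._turn(250.0, 2.0), FS)
        dur = compute_angular_njs(self._turn(100.0, 4.0), FS)
        assert amp == pytest.approx(base, rel=1e-6)
        assert dur == pytest.approx(base, rel=0.01)

    def test_constant_rate_is_zero(self):
        assert compute_angular_njs(np.full(200, 90.0), FS) == 0.0

    def test_zero_turning_angle_undefined(self):
        t = np.linspace(0, 2, 201)
        with pytest.raises(UndefinedFeatureError):
            compute_angular_njs(np.sin(2 * np.pi * t / 2) * 50, FS)


class TestTurnKinematics:
    def test_constant_rate(self):
        ta, mean_v, max_v = compute_turn_kinematics(np.full(201, 90.0), FS)
        assert ta == pytest.approx(180.0, rel=1e-6)
        assert mean_v == pytest.approx(90.0)
        assert max_v == pytest.approx(90.0)

    def test_triangular_pulse(self):
        up = np.linspace(0, 120, 101)
        tri = np.concatenate([up, up[-2::-1]])
        _, mean_v, max_v = compute_turn_kinematics(tri, FS)
        assert max_v == pytest.approx(120.0)
        assert mean_v == pytest.approx(60.0, rel=0.01)

    def test_sign_convention_reports_magnitude(self):
        ta, mean_v, max_v = compute_turn_kinematics(np.full(100, -90.0), FS)
        assert ta > 0 and mean_v > 0 and max_v > 0


class TestRegistries:
    def test_canonical_counts(self):
        assert len(CST30_REGISTRY) == 21 and len(CST30_FEATURES) == 21
        assert len(TUG_REGISTRY) == 28 and len(TUG_FEATURES) == 28

    def test_names_unique(self):
        assert len(set(CST30_FEATURES + TUG_FEATURES)) == 49


class TestExtract30CST:
    def test_noise_free_durations_recovered(self, quiet_cst):
        ann = detect_transitions_30cst(quiet_cst)
        row = extract_30cst_features(quiet_cst, ann)
        assert row["cst_repetitions"] == 7
        assert row["cst_sts_duration_mean"] == pytest.approx(1.0, abs=0.1)
        assert row["cst_sts_duration_sd"] <= 0.05

    def test_empty_annotation_gives_nan_features(self, quiet_cst):
        row = extract_30cst_features(
            quiet_cst, SubphaseAnnotation(test_type="CST30"))
        assert row["cst_repetitions"] == 0
        assert math.isnan(row["cst_sts_duration_mean"])
        assert math.isnan(row["cst_sts_rms_acc_ap"])

    def test_single_repetition_sd_undefined(self, quiet_params):
        p = dataclasses.replace(quiet_params, sit_hold=14.0, stand_hold=12.0)
        rec = simulate_30cst(p, FS, subject_rng(9, 2, 0))
        row = extract_30cst_features(rec, rec.truth)
        assert row["cst_repetitions"] == 1
        assert math.isnan(row["cst_sts_duration_sd"])
        assert row["cst_sts_duration_mean"] > 0

    def test_purity_identical_inputs_identical_outputs(self, default_cst):
        ann = detect_transitions_30cst(default_cst)
        assert extract_30cst_features(default_cst, ann) == \
            extract_30cst_features(default_cst, ann)

    def test_sign_and_unit_invariants(self, default_cst):
        row = extract_30cst_features(default_cst,
                                     detect_transitions_30cst(default_cst))
        for name, val in row.items():
            if math.isnan(val):
                continue
            if "duration" in name or "njs" in name or "rms" in name:
                assert val >= 0, name


class TestExtractTug:
    def test_truth_annotation_durations(self, quiet_tug):
        row = extract_tug_features(quiet_tug, quiet_tug.truth)
        truth_total = (quiet_tug.truth.by_label("TurnToSit")[0].end_s
                       - quiet_tug.truth.by_label("SitToWalk")[0].start_s)
        assert row["tug_total_duration"] == pytest.approx(truth_total, abs=1e-9)
        assert row["tug_turn180_mean_velocity"] > 0
        assert not math.isnan(row["tug_walk_rms_acc_ap"])

    def test_detected_durations_near_truth(self, default_tug):
        ann = segment_tug(default_tug)
        row = extract_tug_features(default_tug, ann)
        for lab, col in (("SitToWalk", "tug_sit_to_walk_duration"),
                         ("Turn180", "tug_turn180_duration"),
                         ("TurnToSit", "tug_turn_to_sit_duration")):
            tru = default_tug.truth.by_label(lab)[0].duration
            assert row[col] == pytest.approx(tru, abs=0.45), col

    def test_turn_peak_matches_generator_parameter(self, quiet_tug,
                                                   quiet_params):
        row = extract_tug_features(quiet_tug, quiet_tug.truth)
        assert row["tug_turn180_max_velocity"] == pytest.approx(
            quiet_params.turn_peak_velocity, rel=0.02)

    def test_empty_annotation_gives_nan_row(self, default_tug):
        row = extract_tug_features(default_tug,
                                   SubphaseAnnotation(test_type="TUG"))
        assert all(math.isnan(v) for v in row.values())

    def test_canonical_column_count(self, default_tug):
        row = extract_tug_features(default_tug, segment_tug(default_tug))
        assert len(row) == 28
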