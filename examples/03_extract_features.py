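"""Extract the canonical movement-quality features from one subject.

Computes the 21-feature 30CST row and the 28-feature TUG row (durations,
RMS intensity, normalized jerk smoothness, turn kinematics, steps) from a
simulated recording pair and prints a readable subset.
"""

from sitstandgo import (
    CohortSpec, detect_transitions_30cst, draw_subject_params,
    extract_30cst_features, extract_tug_features, segment_tug,
    simulate_30cst, simulate_tug,
)
from sitstandgo.synthetic import subject_rng

spec = CohortSpec(n_subjects=2, seed=11)
params = draw_subject_params(0.5, spec, subject_rng(11, 1, 0), "demo")
cst = simulate_30cst(params, 100.0, subject_rng(11, 2, 0))
tug = simulate_tug(params, 100.0, subject_rng(11, 3, 0))

row_cst = extract_30cst_features(cst, detect_transitions_30cst(cst))
row_tug = extract_tug_features(tug, segment_tug(tug))

print(f"30CST features ({len(row_cst)} total):")
for k in ("cst_repetitions", "cst_sts_duration_mean", "cst_sts_duration_sd",
          "cst_sts_njs_acc_ap", "cst_st2si_rms_gyr_ml"):
    print(f"  {k:<28} {row_cst[k]:8.3f}")
print(f"TUG features ({len(row_tug)} total):")
for k in ("tug_total_duration", "tug_walk_duration", "tug_walk_steps",
          "tug_turn180_max_velocity", "tug_tts_turning_angular_njs"):
    print(f"  {k:<28} {row_tug[k]:8.3f}")
# Durations are in seconds, RMS in the sensor's units (m/s^2 or deg/s), the
# acceleration jerk score in metres (lower = smoother) and the angular jerk
# score is dimensionless; velocities are deg/s.
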