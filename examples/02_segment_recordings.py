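"""Segment raw recordings and compare against the generator's ground truth.

Runs the envelope-based transition detector on a 30CST recording and the
turn-qualified segmentation on a TUG recording, then prints detected vs true
boundaries — the agreement shown here is what the feature stage relies on.
"""

from sitstandgo import (
    CohortSpec, detect_transitions_30cst, draw_subject_params, segment_tug,
    simulate_30cst, simulate_tug,
)
from sitstandgo.synthetic import subject_rng

spec = CohortSpec(n_subjects=2, seed=7)
params = draw_subject_params(0.5, spec, subject_rng(7, 1, 0), "demo")

cst = simulate_30cst(params, 100.0, subject_rng(7, 2, 0))
ann = detect_transitions_30cst(cst)
print(f"30CST: {len(cst.truth.intervals)} true transitions, "
      f"{len(ann.intervals)} detected")
err = max(abs(d.midpoint - t.midpoint)
          for d, t in zip(ann.intervals, cst.truth.intervals))
print(f"  worst midpoint error: {err * 1000:.0f} ms")

tug = simulate_tug(params, 100.0, subject_rng(7, 3, 0))
tann = segment_tug(tug)
print("TUG subphases (detected vs truth):")
for lab in ("SitToWalk", "Turn180", "TurnToSitTurning", "TurnToSit"):
    d = tann.by_label(lab)[0]
    t = tug.truth.by_label(lab)[0]
    print(f"  {lab:<18} det [{d.start_s:5.2f}, {d.end_s:5.2f}] "
          f"true [{t.start_s:5.2f}, {t.end_s:5.2f}]")
print(f"  steps detected: {len(tann.steps)}")
# Boundary errors of a few hundredths of a second are expected: the detector
# works on noisy, band-limited envelopes of the raw angular velocity.
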