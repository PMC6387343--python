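"""Simulate one subject's 30-s Chair Stand and Timed Up and Go recordings.

Draws a mid-population subject, renders both tests at 100 Hz and prints the
ground truth the generator knows: how many sit-stand cycles fit into 30 s,
and the timed subphases of the TUG.
"""

from sitstandgo import CohortSpec, draw_subject_params, simulate_30cst, simulate_tug
from sitstandgo.synthetic import subject_rng

spec = CohortSpec(n_subjects=2, seed=42)
params = draw_subject_params(0.5, spec, subject_rng(42, 1, 0), "demo")
print(f"subject latent parameters: sit-to-stand {params.sts_duration_mean:.2f} s, "
      f"cadence {params.cadence:.2f} steps/s, "
      f"turn peak {params.turn_peak_velocity:.0f} deg/s")

cst = simulate_30cst(params, 100.0, subject_rng(42, 2, 0))
reps = len(cst.truth.by_label("SitToStand"))
print(f"30CST: {cst.n_samples} samples, {reps} complete chair rises in 30 s")

tug = simulate_tug(params, 100.0, subject_rng(42, 3, 0))
stw = tug.truth.by_label("SitToWalk")[0]
tts = tug.truth.by_label("TurnToSit")[0]
print(f"TUG:   {tug.duration:.1f} s recording, "
      f"test duration {tts.end_s - stw.start_s:.2f} s, "
      f"{len(tug.truth.steps)} steps")
for iv in tug.truth.intervals:
    print(f"  {iv.label:<18} {iv.start_s:6.2f} .. {iv.end_s:6.2f} s")
# The printed intervals are the generator's ground truth; the segmentation
# stage must recover them from the raw signals alone.
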