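"""Simulate one task session and inspect its event structure.

Builds the block design (1 Hz object images in 10-trial blocks, 3 s gray
baselines, gaps in 60% of gap-block trials at 350/550/750 ms, voluntary and
spontaneous blinks) plus the ground-truth HFB trace of one V1-like and one
face-selective electrode.
"""

import numpy as np

import blinkdeconv as bd

cfg = bd.SimulationConfig(n_blocks=32, seed=7)
truth = bd.GroundTruth.from_rois(["V1", "FC"])
hfb, events = bd.synthetic.generate_hfb_session(cfg, truth)

counts = events["kind"].value_counts()
print(f"session: {cfg.session_duration_s:.0f} s, "
      f"{hfb.values.shape[1]} samples at {hfb.rate:.0f} Hz")
print(f"events: {counts.get('stimulus', 0)} stimuli, "
      f"{counts.get('gap', 0)} gaps, {counts.get('blink', 0)} blinks")
vol = ((events["kind"] == "blink") & (events["subtype"] == "voluntary")).sum()
print(f"of the blinks, {vol} are voluntary (cued blocks) and "
      f"{counts.get('blink', 0) - vol} spontaneous")

gaps = events[events["kind"] == "gap"]
stim_on = events[events["kind"] == "stimulus"].set_index("trial_index")
lat = (gaps["onset_s"].to_numpy() -
       stim_on.loc[gaps["trial_index"], "onset_s"].to_numpy())
print(f"gap latencies used: {sorted(np.unique(np.round(lat, 3)))} s "
      "(the three scheduled positions within the trial)")
print(f"gap durations: {1000 * gaps.eval('offset_s - onset_s').min():.0f}-"
      f"{1000 * gaps.eval('offset_s - onset_s').max():.0f} ms")

# the trace is exactly linear in events: kernels superpose
el = truth.electrodes[0]
print(f"\nground-truth V1 kernels: stimulus peak "
      f"{el.stimulus_kernels['face'].max():.1f}%, dip "
      f"{el.disappearance_kernels['gap'].min():.1f}%, overshoot "
      f"{el.reappearance_kernels['gap'].max():.1f}% "
      "(percent change over the gray-screen baseline)")
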