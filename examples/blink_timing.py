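"""Blink detection and timing from the simulated pupil and EOG channels.

Detects blinks by requiring concurrent pupil-loss and EOG artifacts, times
them at the peak acceleration of the pupil-size change, and matches gaps
with blinks by onset latency (|difference| <= 50 ms) and duration
(|difference| <= 15 ms).
"""

import numpy as np

import blinkdeconv as bd
from blinkdeconv.ocular import detect_blinks_pupil, match_events

cfg = bd.SimulationConfig(n_blocks=16, seed=5)
schedule = bd.synthetic.generate_schedule(cfg)
oc = bd.synthetic.generate_ocular_channels(cfg, schedule)

det = detect_blinks_pupil(oc.pupil, oc.eog, oc.rate)
true_on = oc.true_onsets_s
print(f"{len(true_on)} scheduled blinks, {len(det.blinks)} detected, "
      f"{len(det.ambiguous_intervals)} ambiguous intervals")
err_on = [min(abs(b.onset_s - true_on)) * 1000 for b in det.blinks]
print(f"onset timing error: median {np.median(err_on):.1f} ms "
      f"(peak-acceleration rule on the pupil trace)")

# latency matching on face trials, as used for the matched-event analyses
stim = schedule[schedule["kind"] == "stimulus"].set_index("trial_index")
face = schedule["category"] == "face"
gaps = schedule[(schedule["kind"] == "gap") & face]
blinks = schedule[(schedule["kind"] == "blink") & face]
gap_lat = 1000 * (gaps["onset_s"].to_numpy() -
                  stim.loc[gaps["trial_index"], "onset_s"].to_numpy())
blink_lat = 1000 * (blinks["onset_s"].to_numpy() -
                    stim.loc[blinks["trial_index"], "onset_s"].to_numpy())
res = match_events(gap_lat, blink_lat, tolerance_ms=50.0)
print(f"\nlatency matching (face trials): {len(gap_lat)} gaps x "
      f"{len(blink_lat)} blinks -> {res.n_pairs} pairs; "
      f"paired means {res.mean_gap:.0f} vs {res.mean_blink:.0f} ms")

gap_dur = 1000 * gaps.eval("offset_s - onset_s").to_numpy()
blink_dur = 1000 * blinks.eval("offset_s - onset_s").to_numpy()
res_d = match_events(gap_dur, blink_dur, tolerance_ms=15.0)
print(f"duration matching: {res_d.n_pairs} pairs; paired means "
      f"{res_d.mean_gap:.0f} vs {res_d.mean_blink:.0f} ms")
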