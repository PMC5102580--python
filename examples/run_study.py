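"""End-to-end synthetic study: the gap-vs-blink contrast across ROIs.

Simulates two patients whose ground truth encodes the published morphology
(early visual sites dip and overshoot for gaps and blinks alike; high-level
sites overshoot for gaps only), runs the full pipeline, and prints the
per-ROI pattern of significant electrode-level effects.
"""

from blinkdeconv import experiments as ex

res = ex.headline_pattern(seed=0)
print(f"{res['n_visual']} visually responsive electrodes "
      "across 2 simulated patients\n")

over, dip = res["overshoot"], res["dip"]
print("reappearance overshoot, gap > blink (two-tailed permutation, FDR):")
print(f"  early ROIs (V1-V4, VO):  {over['sig_early']}/{over['n_early']} "
      f"significant; mean gap-blink difference "
      f"{over['mean_observed_early']:+.2f} %*s")
print(f"  high-level ROIs (FC, N-FC): {over['sig_high']}/{over['n_high']} "
      f"significant; mean difference {over['mean_observed_high']:+.2f} %*s")

print("\nactivation dip, blink deeper than gap:")
print(f"  early ROIs:      {dip['sig_early']}/{dip['n_early']} significant; "
      f"mean difference {dip['mean_observed_early']:+.2f} %*s")
print(f"  high-level ROIs: {dip['sig_high']}/{dip['n_high']} significant; "
      f"mean difference {dip['mean_observed_high']:+.2f} %*s")

print(f"\nROI-inhomogeneity statistic for the overshoot effect: "
      f"chi2 = {res['roi_test_overshoot_chi2']:.2f}")
comp = res["components_table"]
summary = comp.groupby(["roi", "interruption", "component"])["split_half"] \
    .mean().round(2)
print("\nmean split-half component integrals (%*s):")
print(summary.to_string())
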