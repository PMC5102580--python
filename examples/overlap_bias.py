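"""Why deconvolution: the overlap bias of naive event-locked averaging.

Places pseudo-events in trials containing no real interruption. Averaging
segments locked to these null events picks up the overlapping 1 Hz stimulus
responses and produces a spurious, highly 'significant' trace; deconvolving
the same pseudo-events against stimulus predictors yields a flat trace with
no FDR-significant lags.
"""

from blinkdeconv import experiments as ex

res = ex.overlap_bias_demo(seed=0)
print(f"{res['n_pseudo_events']} pseudo-events in interruption-free trials")
print(f"naive event-locked average: max |t| = {res['naive_max_t']:.1f} "
      f"(max |value| {res['naive_max_abs']:.1f}%) -> overlap artifact")
print(f"deconvolved pseudo-event trace: max |z| = "
      f"{res['deconvolved_max_abs_z']:.2f}, "
      f"{res['deconvolved_n_significant']} of {res['n_lags']} lags "
      "FDR-significant at q=0.05 -> flat, as it should be")
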