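"""Synthetic live-cell experiment and its fluctuation correlation analysis.

Generates 20 cells x 200 min of three-channel transcription-site traces
(with the experimentally measured shot-noise levels), then runs the
auto/cross-correlation pipeline: shot-noise estimation, dwell times (lag at
which the autocovariance drops below 20%), and the delay of the mRNA signal
behind RNAP2.
"""

import rnapburst as rb

cfg = rb.ExperimentConfig(seed=7)
traces, truth = rb.make_traces(cfg)
corr = rb.aggregate_normalize(traces, max_lag=30)

print(f"{len(traces)} cells, {traces.cells[0].time.size} frames at 1-min sampling")
print("\nShot-noise SD as a multiple of the signal SD (generated at 1.98/1.42/0.41):")
for ch in rb.CHANNELS:
    print(f"  {ch:7s}: {corr.shot_noise_ratio(ch):5.2f}")

print("\nDwell times (min) - mRNA persists longer than RNAP2:")
for ch in rb.CHANNELS:
    dwell, censored = rb.dwell_time(corr.auto_lags, corr.curves[(ch, ch)])
    flag = " (censored)" if censored else ""
    print(f"  {ch:7s}: {dwell:5.2f}{flag}")

delay = rb.cross_delay(corr.cross_lags, corr.curves[("ctd", "mrna")])
print(f"\nmRNA trails the CTD-RNAP2 signal by {delay:.2f} min (cross-corr peak lag)")
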