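"""Transcription-inhibitor phenomenology via rate switching.

Mimics the drug experiments by switching rates mid-simulation: blocking
bursts (initiation inhibitor) drains every signal in the order
CTD -> Ser5ph -> mRNA, while blocking promoter escape (elongation-entry
inhibitor) lets mRNA decay while the promoter cluster persists with large
fluctuations.
"""

import numpy as np

import rnapburst as rb

params = rb.DEFAULT_PARAMS.replace(variant_extras={"k_phos": 2.0})
model = rb.build_model("phospho_step", params)

for mode in ("block_burst", "block_escape"):
    res = rb.perturb(model, mode, t_drug=10.0, duration=60.0, n_cells=100, seed=11)
    pre = res.time < res.t_drug
    print(f"\n=== {mode} (drug at t = {res.t_drug:.0f} min) ===")
    for ch in rb.CHANNELS:
        base = res.mean[ch][pre].mean()
        tail = res.mean[ch][-10:].mean()
        below = np.nonzero(res.mean[ch] < 0.5 * base)[0]
        t_half = res.time[below[0]] - res.t_drug if below.size else np.inf
        print(
            f"  {ch:7s}: pre-drug mean {base:6.2f} -> final {tail:6.2f} "
            f"({100 * tail / base:5.1f}%), half-decay {t_half:5.1f} min after drug"
        )

print(
    "\nBlocking bursts clears the site completely (mRNA last, on the ~5-min\n"
    "completion timescale); blocking escape empties mRNA but retains a\n"
    "fluctuating RNAP2 cluster at the promoter."
)
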