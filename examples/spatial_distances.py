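"""Spatial organization of the three transcription-site signals.

Generates synthetic per-channel centroid tracks (a shared anchor walk plus
fixed inter-channel offsets and localization noise), applies the 50-frame
moving average and 10-min sampling, and reports the median pairwise
separations: the two RNAP2 forms sit close together and well apart from
the site of mRNA synthesis.
"""

import rnapburst as rb

cfg = rb.ExperimentConfig(seed=13)
tracks = rb.make_positions(cfg, n_cells=13)
res = rb.pairwise_distances(tracks, window=50, sample_every=10.0)

print("median separation (nm), generated at 181 / 148 / 93:")
for pair, med in res.medians.items():
    q1, q3 = res.quartiles[pair]
    print(f"  {pair[0]:7s} - {pair[1]:7s}: {med:6.1f}  (IQR {q1:.0f}-{q3:.0f})")
key = (("ctd", "mrna"), ("ctd", "ser5ph"))
print(f"\nMann-Whitney p (ctd-mrna vs ctd-ser5ph distances): {res.p_values[key]:.2e}")
print("The RNAP2 cluster is spatially distinct from nascent mRNA synthesis.")
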