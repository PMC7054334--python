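"""Build spike-in-normalized coverage tracks and a hotspot-anchored profile.

Simulates per-stage fragment sets, extends fragments to 150 bp into 50-bp
binned coverage, rescales every stage by its spike-in factor and prints the
mean H3K4me3 profile around hotspot centers at mid-zygotene.
"""

import numpy as np

from meiodyn.signal import coverage_from_fragments, matrix_around, mean_profile, spike_factors
from meiodyn.synthetic_data import SimConfig, simulate_bundle

bundle = simulate_bundle(SimConfig(seed=3))
factors = spike_factors(bundle.spike_counts)

track, rejected = coverage_from_fragments(bundle.fragments["mZ"], bundle.layout)
track = track.scale(factors["mZ"])
print(f"spike factor (mZ):  {factors['mZ']:.4f}   rejected fragments: {rejected}")
print(f"track mass:         {track.total_mass():.1f}")

strengths = [iv.score for iv in bundle.hotspots]
mat, order = matrix_around(list(bundle.hotspots), track,
                           flank=5000, bin_size=50, rank_scores=strengths)
prof = mean_profile(mat)
center = len(prof) // 2
print(f"matrix shape:       {mat.shape}  (rows ranked by hotspot strength)")
print(f"profile at center:  {prof[center]:.3f}")
print(f"profile at edges:   {np.nanmean([prof[0], prof[-1]]):.3f}")

# The center/edge contrast shows H3K4me3 signal concentrating on hotspot
# centers; rows are ranked by planted hotspot strength the way study
# heatmaps rank hotspots by SPO11-oligo density.
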