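"""Compute the three region-level statistics for one sample.

Uses generator ground truth as a perfectly detected spot table: per region,
the share of total fluorescence (%), puncta per mm^3 per starter neuron,
and the mean distance to each punctum's nine nearest neighbours.
"""

import synaptomap as sm

atlas = sm.make_atlas((32, 128, 128), (1.0, 0.2, 0.2), n_regions=4, seed=1)
# uneven innervation: region 2 receives 4x the input of region 4
densities = {1: 2000.0, 2: 8000.0, 3: 4000.0, 4: 2000.0}
truth = sm.sample_spots(atlas, densities, n_starters=2000, seed=1)

quant = sm.quantify_sample(truth.spots, atlas, n_starters=2000, k=9)
quant["volume_mm3"] = quant["volume_mm3"].map("{:.2e}".format)
print(quant.round(3).to_string(index=False))

profile = sm.axis_profile(
    truth.spots[truth.spots.region_label == 2], atlas, axis="ML", n_bins=8
)
print(f"\nML-axis profile of region 2: counts={profile.bin_counts.tolist()}")
print(f"uniformity p (KS vs uniform) = {profile.uniformity_p:.3f}")
# Densities recover the generative values up to Poisson noise, and the
# average distance shrinks in the densest region (regions under 10 puncta
# report NaN). The low KS p is real: puncta placed uniformly per unit
# volume pile up where the region's ellipsoid cross-section is widest, so
# their 1D marginal along the axis is not uniform.
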