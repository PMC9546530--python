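"""Simulate an fMOST-like volume and detect the puncta in it.

Builds a small synthetic brain (ellipsoid mask, 4 regions), scatters
presynaptic puncta at a realistic density, renders them as 0.8 um Gaussians
at 0.2 x 0.2 x 1 um voxels with Poisson + read noise, then runs the LoG
detector and scores it against the generator's ground truth.
"""

import synaptomap as sm

shape, voxel = (32, 256, 256), (1.0, 0.2, 0.2)
atlas = sm.make_atlas(shape, voxel, n_regions=4, seed=0)
densities = {label: 4000.0 for label in atlas.region_labels()}  # per mm^3 per neuron
truth = sm.sample_spots(atlas, densities, n_starters=2000, seed=0)

config = sm.SyntheticConfig(volume_shape=shape, voxel_size=voxel, n_regions=4, seed=0)
volume = sm.render_volume(truth, config)

detected = sm.detect_spots(volume)  # default: 0.8 um spots, 1 um split-touching
metrics = sm.match_spots(detected, truth.spots, match_radius_um=0.5)

print(f"ground-truth puncta : {len(truth.spots)}")
print(f"detected puncta     : {len(detected)}")
print(f"precision / recall  : {metrics['precision']:.3f} / {metrics['recall']:.3f}")
print(f"F1 at 0.5 um        : {metrics['f1']:.3f}")
print(f"median error        : {metrics['median_error_um']:.3f} um")
# F1 near 1 means nearly every rendered punctum is found, with sub-voxel
# localisation despite the 5x anisotropic z sampling.
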