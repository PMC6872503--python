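"""Occlusion relevance map and region-of-interest extraction.

Trains a classifier on a planted-signal cohort, slides a 3^3 occlusion patch
over held-out case volumes (replacing each patch with multivariate-normal
draws estimated from control volumes), scores every window with the log-odds
relevance d = log[(p0/(1-p0)) / (p1/(1-p1))], and extracts the top-decile
connected regions.
"""

import neurocausal as nc

spec = nc.ImageCohortSpec(grid_shape=(32, 32, 32), n_cases=20, n_controls=20,
                          signal_regions=(((10, 22), (10, 22), (10, 22)),),
                          effect_size=5.0, noise_sd=1.0, smoothness_sigma=1.0,
                          seed=1)
volumes, labels, truth = nc.generate_image_cohort(spec)

arch = nc.ArchitectureConfig(conv_specs=((7, 4, 4, 8), (3, 1, 1, 16),
                                         (3, 1, 1, 16)), n_maxpool=3)
model = nc.build_classifier(arch, input_shape=spec.grid_shape, seed=1)
nc.train_classifier(model, volumes, labels,
                    nc.TrainConfig(learning_rate=1e-3, epochs=10, batch_size=8),
                    seed=1)

sampler = nc.PatchSampler(volumes[labels == 0], n_draws=4)
rmap = nc.compute_relevance_map(model, volumes[labels == 1][:4], sampler,
                                stride=3, seed=1)
rois = nc.select_top_regions(rmap, percentile=90)

mask = truth.region_mask(spec.grid_shape)
dice = nc.dice_coefficient(rois.mask(spec.grid_shape), mask)
print(f"{len(rois)} regions above the 90th percentile of relevance")
print(f"largest region: {rois.rois[0].size} voxels, bounding box {rois.rois[0].bbox}")
print(f"Dice overlap between top-decile regions and the planted box: {dice:.3f}")
print(f"mean relevance inside planted box {rmap.W[mask].mean():+.4f} "
      f"vs outside {rmap.W[~mask].mean():+.4f}")
# Dice well above chance and a clearly higher in-box relevance mean show the
# occlusion analysis localizes the voxels the classifier actually uses.
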