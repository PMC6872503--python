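"""Train the 3D convolutional classifier and cross-validate it.

Uses a reduced convolutional schedule on a 16^3 cohort so the whole script
runs in seconds; the native-resolution schedule (11/5/3/3/3 filters, stride 4
first, five max pools, global average pooling) is the package default.
"""

import neurocausal as nc

spec = nc.ImageCohortSpec(grid_shape=(16, 16, 16), n_cases=15, n_controls=15,
                          signal_regions=(((4, 11), (4, 11), (4, 11)),),
                          effect_size=5.0, noise_sd=1.0, smoothness_sigma=1.0,
                          seed=7)
volumes, labels, _ = nc.generate_image_cohort(spec)

arch = nc.ArchitectureConfig(conv_specs=((5, 2, 2, 6), (3, 1, 1, 8)), n_maxpool=2)
per_fold, mean = nc.crossvalidate(
    volumes, labels, k=5, seed=0, cfg=arch,
    train_cfg=nc.TrainConfig(learning_rate=1e-3, epochs=10, batch_size=8))

print("fivefold cross-validation on the planted-signal cohort:")
for m in per_fold:
    print(f"  fold {m.fold}: accuracy {m.accuracy:.3f}  "
          f"sensitivity {m.sensitivity:.3f}  specificity {m.specificity:.3f}")
print(f"mean accuracy {mean.accuracy:.3f}, mean AUC {mean.auc:.3f}")
# Accuracy near 1 confirms the planted signal is separable; AUC is the
# rank statistic on the predicted disease probability.
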