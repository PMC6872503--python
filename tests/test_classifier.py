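"""3D classifier: architecture contracts, training, metrics, cross-validation."""

import numpy as np
import pytest

import neurocausal as nc
from neurocausal.classifier import (ConfigurationError, evaluate,
                                    load_classifier, save_classifier)
from neurocausal.synthetic import ValidationError


class ConstantPredictor:
    def __init__(self, p):
        self.p = p

    def predict_disease_probability(self, volumes):
        n = len(np.asarray(volumes))
        return np.full(n, self.p)


class TestArchitecture:
    def test_default_model_on_native_grid(self):
        model = nc.build_classifier(input_shape=(91, 109, 91), seed=0)
        x = np.random.default_rng(0).standard_normal((2, 91, 109, 91))
        p = model.predict_proba(x)
        assert p.shape == (2, 2)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_weights_give_even_odds(self):
        model = nc.build_classifier(input_shape=(16, 16, 16), seed=0,
                                    cfg=nc.ArchitectureConfig(
                                        conv_specs=((5, 2, 2, 4), (3, 1, 1, 4)),
                                        n_maxpool=2))
        for p, _ in model.net.params():
            p[...] = 0.0
        probs = model.predict_proba(np.ones((3, 16, 16, 16)))
        assert np.allclose(probs, 0.5)

    def test_parameter_count_matches_hand_calculation(self):
        # independent layer-by-layer arithmetic for the default schedule
        channels = [1, 16, 32, 64, 64, 64]
        kernels = [11, 5, 3, 3, 3]
        expected = sum(co * ci * k ** 3 + co
                       for ci, co, k in zip(channels, channels[1:], kernels))
        expected += 64 * 2 + 2  # GAP head
        model = nc.build_classifier(input_shape=(91, 109, 91), seed=1)
        assert model.n_parameters == expected

    def test_too_small_input_names_offending_layer(self):
        with pytest.raises(ConfigurationError, match="conv1"):
            nc.build_classifier(input_shape=(8, 8, 8), seed=0)

    def test_fc_head_option(self):
        cfg = nc.ArchitectureConfig(conv_specs=((5, 2, 2, 4), (3, 1, 1, 4)),
                                    n_maxpool=2, gap=False, fc_widths=(16, 8))
        model = nc.build_classifier(cfg, input_shape=(16, 16, 16), seed=0)
        p = model.predict_proba(np.zeros((2, 16, 16, 16)))
        assert p.shape == (2, 2) and np.allclose(p.sum(axis=1), 1.0)


class TestTraining:
    def test_strong_signal_reaches_high_training_accuracy(self, strong_cohort_16, tiny_arch):
        _, vols, labels, _ = strong_cohort_16
        model = nc.build_classifier(tiny_arch, input_shape=(16, 16, 16), seed=0)
        nc.train_classifier(model, vols, labels,
                            nc.TrainConfig(learning_rate=1e-3, epochs=12, batch_size=8),
                            seed=0)
        assert evaluate(model, vols, labels).accuracy >= 0.95

    def test_zero_epochs_leaves_model_untouched(self, tiny_arch):
        model = nc.build_classifier(tiny_arch, input_shape=(12, 12, 12), seed=3)
        before = model.net.state()
        rng = np.random.default_rng(0)
        nc.train_classifier(model, rng.standard_normal((4, 12, 12, 12)),
                            np.array([0, 1, 0, 1]), nc.TrainConfig(epochs=0), seed=0)
        assert all(np.array_equal(a, b) for a, b in zip(before, model.net.state()))

    def test_single_class_rejected(self, tiny_arch):
        model = nc.build_classifier(tiny_arch, input_shape=(12, 12, 12), seed=0)
        with pytest.raises(ValidationError):
            nc.train_classifier(model, np.zeros((3, 12, 12, 12)), np.ones(3, int))

    def test_training_is_seed_deterministic(self, tiny_arch):
        rng = np.random.default_rng(5)
        vols = rng.standard_normal((6, 12, 12, 12))
        labels = np.array([0, 1] * 3)
        states = []
        for _ in range(2):
            model = nc.build_classifier(tiny_arch, input_shape=(12, 12, 12), seed=4)
            nc.train_classifier(model, vols, labels,
                                nc.TrainConfig(epochs=2, batch_size=3), seed=4)
            states.append(model.net.state())
        assert all(np.array_equal(a, b) for a, b in zip(*states))

    def test_save_load_roundtrip(self, tiny_arch, tmp_path):
        model = nc.build_classifier(tiny_arch, input_shape=(12, 12, 12), seed=2)
        x = np.random.default_rng(1).standard_normal((2, 12, 12, 12))
        save_classifier(model, tmp_path / "m.npz")
        loaded = load_classifier(tmp_path / "m.npz")
        assert np.allclose(model.predict_proba(x), loaded.predict_proba(x))


class TestMetrics:
    def test_perfect_predictor(self):
        labels = np.array([1, 1, 0, 0])
        m = evaluate(ConstantPredictorFromLabels(labels), np.zeros((4, 2, 2, 2)), labels)
        assert (m.accuracy, m.sensitivity, m.specificity, m.auc) == (1, 1, 1, 1)

    def test_always_control_predictor_on_imbalanced_cohort(self):
        labels = np.r_[np.ones(51, int), np.zeros(100, int)]
        m = evaluate(ConstantPredictor(0.0), np.zeros((151, 2, 2, 2)), labels)
        assert m.accuracy == pytest.approx(100 / 151)
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0

    def test_random_scores_have_auc_half_on_average(self):
        labels = np.r_[np.ones(30, int), np.zeros(30, int)]
        aucs = []
        for seed in range(100):
            pred = RandomPredictor(seed)
            aucs.append(evaluate(pred, np.zeros((60, 2, 2, 2)), labels).auc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_missing_class_reports_missing_not_zero(self):
        labels = np.zeros(5, int)
        m = evaluate(ConstantPredictor(0.2), np.zeros((5, 2, 2, 2)), labels)
        assert m.sensitivity is None and m.auc is None
        assert m.specificity == 1.0


class ConstantPredictorFromLabels:
    def __init__(self, labels):
        self.labels = np.asarray(labels, float)

    def predict_disease_probability(self, volumes):
        return self.labels


class RandomPredictor:
    def __init__(self, seed):
        self.rng = np.random.default_rng(seed)

    def predict_disease_probability(self, volumes):
        return self.rng.uniform(size=len(np.asarray(volumes)))


class TestCrossValidation:
    def test_every_subject_in_exactly_one_test_fold(self):
        from neurocausal.classifier import _stratified_folds
        labels = np.r_[np.ones(51, int), np.zeros(100, int)]
        folds = _stratified_folds(labels, 5, np.random.default_rng(0))
        assert len(folds) == 151
        assert set(folds) == set(range(5))
        for c in (0, 1):
            sizes = np.bincount(folds[labels == c], minlength=5)
            assert sizes.max() - sizes.min() <= 1

    def test_strong_signal_cv_accuracy(self, strong_cohort_16, tiny_arch):
        _, vols, labels, _ = strong_cohort_16
        per_fold, mean = nc.crossvalidate(
            vols, labels, k=5, seed=0, cfg=tiny_arch,
            train_cfg=nc.TrainConfig(learning_rate=1e-3, epochs=10, batch_size=8))
        assert mean.accuracy >= 0.9
        assert len(per_fold) == 5

    def test_permuted_labels_score_near_chance(self, tiny_arch):
        # balanced 60-subject cohort, labels shuffled: CV accuracy should sit
        # in the permutation-null band around 0.5
        spec = nc.ImageCohortSpec(grid_shape=(16, 16, 16), n_cases=30, n_controls=30,
                                  signal_regions=(((4, 11), (4, 11), (4, 11)),),
                                  effect_size=5.0, noise_sd=1.0,
                                  smoothness_sigma=1.0, seed=13)
        vols, labels, _ = nc.generate_image_cohort(spec)
        permuted = np.random.default_rng(0).permutation(labels)
        _, mean = nc.crossvalidate(
            vols, permuted, k=5, seed=1, cfg=tiny_arch,
            train_cfg=nc.TrainConfig(learning_rate=1e-3, epochs=6, batch_size=8))
        assert 0.35 <= mean.accuracy <= 0.65

    def test_metrics_invariant_to_subject_ordering(self, tiny_arch):
        rng = np.random.default_rng(2)
        vols = rng.standard_normal((20, 12, 12, 12))
        labels = np.r_[np.ones(10, int), np.zeros(10, int)]
        ids = [f"S{i:03d}" for i in range(20)]
        _, m1 = nc.crossvalidate(vols, labels, k=2, seed=3, cfg=tiny_arch,
                                 train_cfg=nc.TrainConfig(epochs=2),
                                 subject_ids=ids)
        perm = rng.permutation(20)
        _, m2 = nc.crossvalidate(vols[perm], labels[perm], k=2, seed=3,
                                 cfg=tiny_arch, train_cfg=nc.TrainConfig(epochs=2),
                                 subject_ids=[ids[i] for i in perm])
        assert m1.accuracy == m2.accuracy and m1.auc == m2.auc

    def test_augmented_copies_never_leak_into_test_folds(self, tiny_arch):
        rng = np.random.default_rng(4)
        vols = rng.standard_normal((12, 12, 12, 12))
        labels = np.r_[np.ones(6, int), np.zeros(6, int)]
        aug = nc.AugmentationConfig(blur_settings=((3, 0.7),),
                                    translation_voxels=0, balance=True)
        # crossvalidate asserts internally that augmented training subject ids
        # are disjoint from the test fold; this runs that path end to end
        per_fold, _ = nc.crossvalidate(vols, labels, k=3, seed=0, cfg=tiny_arch,
                                       train_cfg=nc.TrainConfig(epochs=1),
                                       augment_cfg=aug)
        assert len(per_fold) == 3

    def test_k_larger_than_class_rejected(self, tiny_arch):
        with pytest.raises(ValidationError):
            nc.crossvalidate(np.zeros((4, 12, 12, 12)), np.array([1, 1, 0, 0]),
                             k=3, cfg=tiny_arch)
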