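import numpy as np
import pytest

from gaitbalance.classifier import (
    ModelConfig, build_classifier, load_model, predict, save_model,
    train_classifier,
)
from gaitbalance.preprocessing import PreprocessedSample, preprocess_dataset


def _constant_samples(n_per_class, n_joints=4, window=20, labels=(0, 1, 2),
                      subject=0):
    """Linearly separable classes: constant tensors at distinct offsets."""
    samples = []
    for label in labels:
        for i in range(n_per_class):
            tensor = np.full((window, n_joints, 3), (label - 1) * 0.8)
            tensor += np.random.default_rng(label * 100 + i).normal(
                0, 0.01, tensor.shape)
            samples.append(PreprocessedSample(
                tensor=tensor, label=label, subject_id=subject + i % 2,
                trial_id=i, group="A0"))
    return samples


class TestConfigValidation:
    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            ModelConfig(kernel_sizes=(4, 3, 1))

    def test_dropout_one_rejected(self):
        with pytest.raises(ValueError, match="dropout"):
            ModelConfig(dropout_rate=1.0)

    def test_defaults_follow_published_setup(self):
        cfg = ModelConfig()
        assert cfg.kernel_sizes == (5, 3, 1)
        assert cfg.channels == 64
        assert cfg.n_blocks == 3
        assert cfg.optimizer == "adam"
        assert cfg.learning_rate == 1e-4


class TestArchitecture:
    def test_first_block_maps_63_to_64_channels(self):
        model = build_classifier(ModelConfig(), n_joints=21)
        blk = model.blocks[0]
        assert blk.conv1.c_in == 63
        assert blk.conv1.c_out == 64
        assert blk.proj is not None  # channel mismatch needs projection
        assert model.blocks[1].proj is None

    def test_output_shape_is_batch_by_classes(self, quick_config):
        model = build_classifier(quick_config, n_joints=5)
        x = np.random.default_rng(0).normal(size=(5, 20, 5, 3))
        assert model.logits(x).shape == (5, 3)

    def test_zero_weights_give_uniform_softmax(self, quick_config):
        model = build_classifier(quick_config, n_joints=4)
        for p in model.params:
            p[...] = 0.0
        x = np.random.default_rng(1).normal(size=(3, 20, 4, 3))
        probs, _ = predict(model, x)
        assert np.allclose(probs, 1.0 / 3.0)

    def test_geometry_mismatch_rejected(self, quick_config):
        model = build_classifier(quick_config, n_joints=4)
        x = np.zeros((2, 20, 7, 3))
        with pytest.raises(ValueError, match="geometry"):
            model.logits(x)

    def test_channel_layout_round_trips(self, quick_config):
        model = build_classifier(quick_config, n_joints=4)
        x = np.random.default_rng(2).normal(size=(2, 20, 4, 3))
        assert np.allclose(model.from_channels(model.to_channels(x)), x,
                           atol=1e-6)

    def test_affine_when_relus_disabled(self):
        """With identity activations, inference BN and no dropout the network
        is affine: f(a*x) - f(0) is linear in a."""
        cfg = ModelConfig(channels=6, n_blocks=2, dropout_rate=0.0,
                          activation="identity", seed=3)
        model = build_classifier(cfg, n_joints=4)
        x = np.random.default_rng(3).normal(size=(1, 20, 4, 3))
        f = lambda arr: model.logits(arr).astype(np.float64)
        f0 = f(x * 0.0)
        g1 = f(x) - f0
        g3 = f(3.0 * x) - f0
        assert np.allclose(g3, 3.0 * g1, rtol=1e-3, atol=1e-4)


class TestTraining:
    def test_learns_linearly_separable_constant_classes(self):
        """Separable constant-signal classes reach 100% training accuracy
        in the majority of 3 seeds."""
        wins = 0
        for seed in (0, 1, 2):
            cfg = ModelConfig(channels=8, n_blocks=1, max_epochs=50,
                              patience=50, learning_rate=1e-3,
                              dropout_rate=0.0, seed=seed)
            train = _constant_samples(6, subject=0)
            val = _constant_samples(2, subject=5)
            model = build_classifier(cfg, n_joints=4)
            model, _ = train_classifier(model, train, val, cfg)
            _, pred = predict(model, train)
            if np.mean(pred == [s.label for s in train]) == 1.0:
                wins += 1
        assert wins >= 2

    def test_best_epoch_minimizes_validation_loss(self, quick_config):
        train = _constant_samples(4, subject=0)
        val = _constant_samples(2, subject=5)
        model = build_classifier(quick_config, n_joints=4)
        _, hist = train_classifier(model, train, val, quick_config)
        assert hist.val_loss[hist.best_epoch] == min(hist.val_loss)

    def test_training_is_deterministic_given_seed(self, quick_config):
        train = _constant_samples(4, subject=0)
        val = _constant_samples(2, subject=5)
        results = []
        for _ in range(2):
            model = build_classifier(quick_config, n_joints=4)
            model, _ = train_classifier(model, train, val, quick_config)
            results.append([p.copy() for p in model.params])
        for a, b in zip(*results):
            assert np.array_equal(a, b)

    def test_subject_overlap_between_train_and_val_rejected(self, quick_config):
        samples = _constant_samples(4, subject=0)
        model = build_classifier(quick_config, n_joints=4)
        with pytest.raises(ValueError, match="overlap"):
            train_classifier(model, samples, samples, quick_config)

    def test_empty_split_rejected(self, quick_config):
        model = build_classifier(quick_config, n_joints=4)
        with pytest.raises(ValueError, match="non-empty"):
            train_classifier(model, [], _constant_samples(1), quick_config)


class TestPrediction:
    def test_probabilities_are_normalized(self, quick_config):
        model = build_classifier(quick_config, n_joints=4)
        x = np.random.default_rng(5).normal(size=(7, 20, 4, 3))
        probs, _ = predict(model, x)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_duplicate_samples_get_identical_predictions(self, quick_config):
        model = build_classifier(quick_config, n_joints=4)
        x = np.random.default_rng(6).normal(size=(1, 20, 4, 3))
        both = np.concatenate([x, x])
        probs, labels = predict(model, both)
        assert np.array_equal(probs[0], probs[1])
        assert labels[0] == labels[1]

    def test_predictions_invariant_to_walkway_offset(self, small_dataset,
                                                     quick_config):
        """Translating the raw walk before preprocessing must not change
        the prediction (pelvis re-centering removes the offset)."""
        from dataclasses import replace
        seq = small_dataset.samples[0]
        shifted = replace(seq, frames=seq.frames + np.array([2.0, 0.5, -1.0]))
        samples = preprocess_dataset(small_dataset, "A0")
        model = build_classifier(quick_config, n_joints=21)
        from gaitbalance.preprocessing import preprocess
        pa, _ = predict(model, [preprocess(seq, "A0")])
        pb, _ = predict(model, [preprocess(shifted, "A0")])
        assert np.allclose(pa, pb, atol=1e-5)


def test_model_round_trips_through_disk(tmp_path, quick_config):
    train = _constant_samples(4, subject=0)
    val = _constant_samples(2, subject=5)
    model = build_classifier(quick_config, n_joints=4)
    model, _ = train_classifier(model, train, val, quick_config)
    save_model(model, tmp_path / "model.npz")
    back = load_model(tmp_path / "model.npz")
    x = np.random.default_rng(7).normal(size=(3, 20, 4, 3))
    assert np.allclose(model.logits(x), back.logits(x), atol=1e-6)
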