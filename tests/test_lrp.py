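"""Relevance-propagation checks: closed-form oracles on toy affine models,
conservation through the full network, and contribution-matrix layout."""

import numpy as np
import pytest

from gaitbalance.classifier import ModelConfig, build_classifier
from gaitbalance.lrp import (
    contribution_matrix, conservation_check, relevance, zrule_conv,
    zrule_dense, zrule_pool, _folded_forward,
)
from gaitbalance.preprocessing import PreprocessedSample


def _sample(n_joints=4, seed=0, group="A0"):
    rng = np.random.default_rng(seed)
    return PreprocessedSample(
        tensor=rng.normal(size=(20, n_joints, 3)), label=0,
        subject_id=0, trial_id=0, group=group,
    )


def _linearized(n_joints=4, seed=5, n_blocks=2, channels=6):
    """Identity-activation classifier with all biases and BN shifts zeroed:
    a purely linear, bias-free map from input to logits."""
    cfg = ModelConfig(channels=channels, n_blocks=n_blocks, dropout_rate=0.0,
                      activation="identity", seed=seed)
    model = build_classifier(cfg, n_joints)
    for blk in model.blocks:
        for conv, bn in ((blk.conv1, blk.bn1), (blk.conv2, blk.bn2),
                         (blk.conv3, blk.bn3)):
            conv.bias[...] = 0.0
            bn.beta[...] = 0.0
            bn.running_mean[...] = 0.0
    model.dense.bias[...] = 0.0
    return model


class TestZRuleOracles:
    def test_identity_dense_passes_relevance_straight_through(self):
        """Diagonal map, input (1, 0): all relevance stays on the active
        input and equals the output score."""
        a = np.array([[1.0, 0.0]])
        w = np.eye(2)
        r_out = np.array([[1.0, 0.0]])  # explain class 0, score = 1
        r = zrule_dense(a, w, r_out, eps=0.0)
        assert np.allclose(r, [[1.0, 0.0]])
        assert np.isclose(r.sum(), 1.0)

    def test_zero_input_gives_zero_relevance(self):
        a = np.zeros((1, 3))
        w = np.random.default_rng(0).normal(size=(2, 3))
        r = zrule_dense(a, w, np.array([[1.0, 0.0]]), eps=0.0)
        assert np.allclose(r, 0.0)

    def test_relevance_scales_linearly_with_target_relevance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(1, 5))
        w = rng.normal(size=(3, 5))
        r_out = rng.normal(size=(1, 3))
        r1 = zrule_dense(a, w, r_out, eps=0.0)
        r3 = zrule_dense(a, w, 3.0 * r_out, eps=0.0)
        assert np.allclose(r3, 3.0 * r1)

    @pytest.mark.parametrize("rule,shape_a,shape_r", [
        ("conv", (1, 3, 8), (1, 4, 8)),
        ("pool", (1, 5, 8), (1, 5)),
    ])
    def test_rules_conserve_relevance_at_eps_zero(self, rule, shape_a, shape_r):
        rng = np.random.default_rng(2)
        a = rng.normal(size=shape_a)
        r_out = rng.normal(size=shape_r)
        if rule == "conv":
            w = rng.normal(size=(4, 3, 3))
            r_in = zrule_conv(a, w, r_out, eps=0.0)
        else:
            r_in = zrule_pool(a, r_out, eps=0.0)
        assert np.isclose(r_in.sum(), r_out.sum(), rtol=1e-9)


class TestLinearNetworkOracle:
    def test_relevance_equals_input_times_gradient(self):
        """On a bias-free affine network, eps=0 relevance is exactly
        input (.) gradient of the target score (finite-difference probes)."""
        model = _linearized()
        sample = _sample()
        a = model.to_channels(sample.tensor[None]).astype(np.float64)
        _, _, _, logits = _folded_forward(model, a)
        target = int(logits[0].argmax())
        rmap = relevance(model, sample, target_class=target, epsilon=0.0)
        rel = model.to_channels(rmap.relevance[None]).astype(np.float64)

        rng = np.random.default_rng(3)
        for _ in range(15):
            idx = tuple(rng.integers(0, s) for s in a.shape)
            probe = np.zeros_like(a)
            probe[idx] = 1.0
            _, _, _, shifted = _folded_forward(model, a + probe)
            grad_i = shifted[0, target] - logits[0, target]  # exact: linear map
            assert np.isclose(rel[idx], a[idx] * grad_i, rtol=1e-6, atol=1e-9)

    def test_conservation_exact_on_linear_network(self):
        model = _linearized(seed=7)
        sample = _sample(seed=7)
        rmap = relevance(model, sample, epsilon=0.0, compensate=False)
        assert np.isclose(rmap.total, rmap.target_score, rtol=1e-7)


class TestFullNetworkConservation:
    def test_gap_small_on_trained_default_model(self, trained_default_model):
        """The documented tolerance for the trained network is 1e-2."""
        model, samples, fold = trained_default_model
        test = [s for s in samples if s.subject_id == fold.test_subject]
        gaps = [conservation_check(relevance(model, s), model, s)
                for s in test[:10]]
        assert max(gaps) <= 1e-2

    def test_gap_invariant_under_sample_duplication(self, trained_default_model):
        model, samples, _ = trained_default_model
        s = samples[0]
        g1 = conservation_check(relevance(model, s), model, s)
        g2 = conservation_check(relevance(model, s), model, s)
        assert g1 == g2

    def test_relevance_values_are_finite(self, trained_default_model):
        model, samples, _ = trained_default_model
        rmap = relevance(model, samples[5])
        assert np.all(np.isfinite(rmap.relevance))
        assert rmap.relevance.shape == (20, 21, 3)


class TestContributionMatrix:
    def test_h4_matrix_has_39_rows(self):
        rng = np.random.default_rng(4)
        from gaitbalance.lrp import RelevanceMap
        maps = [RelevanceMap(rng.normal(size=(20, 13, 3)), 0, 1.0, 0, 0.0, "H4")
                for _ in range(3)]
        cm = contribution_matrix(maps, level=0)
        assert cm.matrix.shape == (39, 20)
        assert cm.row_labels[0] == "X_PELVIS"
        assert len(cm.row_labels) == 39

    def test_mean_absolute_aggregation_is_non_negative(self):
        from gaitbalance.lrp import RelevanceMap
        rng = np.random.default_rng(5)
        maps = [RelevanceMap(rng.normal(size=(20, 3, 3)), 0, 1.0, 0, 0.0, "G1")
                for _ in range(4)]
        assert contribution_matrix(maps).matrix.min() >= 0.0

    def test_single_concentrated_map_lights_one_cell(self):
        from gaitbalance.lrp import RelevanceMap
        rel = np.zeros((20, 3, 3))
        rel[7, 1, 2] = 4.2  # frame 7, joint 1, z axis
        cm = contribution_matrix(
            [RelevanceMap(rel, 0, 1.0, 0, 0.0, "G1")])
        nonzero = np.argwhere(cm.matrix != 0)
        assert nonzero.tolist() == [[2 * 3 + 1, 7]]  # z block, joint row 1

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            contribution_matrix([])

    def test_mixed_geometry_rejected(self):
        from gaitbalance.lrp import RelevanceMap
        rng = np.random.default_rng(6)
        maps = [RelevanceMap(rng.normal(size=(20, 3, 3)), 0, 1.0, 0, 0.0, "G1"),
                RelevanceMap(rng.normal(size=(20, 13, 3)), 0, 1.0, 0, 0.0, "H4")]
        with pytest.raises(ValueError, match="mixed"):
            contribution_matrix(maps)
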