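"""Contrastive losses against closed forms and brute-force oracles."""

import autograd.numpy as anp
import numpy as np
import pytest
from autograd import grad

from ecgcl.losses import (ContrastiveBatch, LossConfig, LossWeights,
                          channel_loss, combined_loss, cosine_sim,
                          cross_entropy, label_loss, one_hot, temporal_loss)
from oracles import (channel_loss_ref, cross_entropy_ref, label_loss_ref,
                     temporal_loss_ref)


def _unit_rows(rng, *shape):
    x = rng.standard_normal(shape)
    return x / np.linalg.norm(x, axis=-1, keepdims=True)


class TestCosineSim:
    def test_self_similarity_is_one(self):
        v = np.array([0.3, -2.0, 1.0])
        assert cosine_sim(v, v) == pytest.approx(1.0)

    def test_orthogonal_is_zero_and_example(self):
        assert cosine_sim(np.array([1.0, 0]), np.array([0.0, 1])) == pytest.approx(0.0)
        assert cosine_sim(np.array([1.0, 0]), np.array([1.0, 1])) == \
            pytest.approx(1 / np.sqrt(2))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_sim(np.zeros(3), np.ones(3))


class TestClosedForms:
    def test_temporal_single_sample_single_timestep_is_zero(self):
        h = np.random.default_rng(0).standard_normal((1, 1, 4))
        assert float(temporal_loss(h, h.copy(), tau=1.0)) == pytest.approx(0.0, abs=1e-7)

    def test_temporal_orthonormal_pair(self):
        # identical views, two mutually orthonormal timestep vectors, tau=1:
        # each term is -log(e / (e + 2))
        h = np.eye(2)[None, :, :]
        expected = np.log(1 + 2 / np.e)
        assert float(temporal_loss(h, h.copy(), 1.0)) == pytest.approx(expected, rel=1e-6)

    def test_channel_single_sample_is_zero(self):
        z = _unit_rows(np.random.default_rng(1), 1, 8)
        assert float(channel_loss(z, z.copy(), 0.1)) == pytest.approx(0.0, abs=1e-7)

    def test_channel_orthonormal_pair(self):
        z = np.eye(2)
        expected = np.log(1 + 2 / np.e)
        assert float(channel_loss(z, z.copy(), 1.0)) == pytest.approx(expected, rel=1e-6)

    def test_label_three_identical_same_label(self):
        z = np.tile([1.0, 0.0, 0.0], (3, 1))
        assert float(label_loss(z, [1, 1, 1], 0.35)) == pytest.approx(np.log(2), rel=1e-6)

    def test_label_two_different_labels_is_zero_with_warning(self):
        z = _unit_rows(np.random.default_rng(2), 2, 4)
        with pytest.warns(UserWarning):
            assert float(label_loss(z, [0, 1], 0.1)) == 0.0

    def test_cross_entropy_uniform_binary(self):
        scores = np.zeros((1, 2))
        assert float(cross_entropy(scores, np.array([[1.0, 0.0]]))) == \
            pytest.approx(-2 * np.log(0.5), rel=1e-6)

    def test_cross_entropy_perfect_prediction_near_zero(self):
        scores = np.array([[50.0, -50.0], [-50.0, 50.0]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert float(cross_entropy(scores, y)) < 1e-5


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(10))
    def test_all_losses_match_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        B, T, D = rng.integers(2, 9), rng.integers(2, 9), rng.integers(2, 17)
        h = rng.standard_normal((B, T, D))
        ht = rng.standard_normal((B, T, D))
        z = _unit_rows(rng, B, D)
        zp = _unit_rows(rng, B, D)
        labels = rng.integers(0, 2, size=B)
        tau_t, tau = 1.0, 0.1
        assert float(temporal_loss(h, ht, tau_t)) == \
            pytest.approx(temporal_loss_ref(h, ht, tau_t), rel=1e-6)
        assert float(channel_loss(z, zp, tau)) == \
            pytest.approx(channel_loss_ref(z, zp, tau), rel=1e-6)
        assert float(label_loss(z, labels, tau)) == \
            pytest.approx(label_loss_ref(z, labels, tau), rel=1e-6, abs=1e-9)
        scores = rng.standard_normal((B, 2))
        oh = one_hot(labels)
        assert float(cross_entropy(scores, oh)) == \
            pytest.approx(cross_entropy_ref(scores, oh), rel=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(100 + seed)
        B, T, D = 6, 4, 8
        h, ht = rng.standard_normal((2, B, T, D))
        z, zt, zp = (_unit_rows(rng, B, D) for _ in range(3))
        labels = rng.integers(0, 2, size=B)
        perm = rng.permutation(B)
        batch = ContrastiveBatch(h, ht, z, zt, zp, labels)
        permuted = ContrastiveBatch(h[perm], ht[perm], z[perm], zt[perm],
                                    zp[perm], labels[perm])
        cfg = LossConfig()
        a, _ = combined_loss(batch, cfg, is_labeled=True)
        b, _ = combined_loss(permuted, cfg, is_labeled=True)
        assert float(a) == pytest.approx(float(b), rel=1e-6)

    def test_high_temperature_limit_matches_oracle(self):
        # tau -> inf flattens all similarities: the loss approaches
        # log(n_denominator_terms), here log(2T - 1) per anchor
        rng = np.random.default_rng(7)
        h, ht = rng.standard_normal((2, 3, 5, 6))
        big = 1e6
        assert float(temporal_loss(h, ht, big)) == \
            pytest.approx(np.log(2 * 5 - 1), rel=1e-4)


class TestCombinedLoss:
    def _batch(self, rng, labeled=True):
        B, T, D = 4, 3, 6
        h, ht = rng.standard_normal((2, B, T, D))
        z, zt, zp = (_unit_rows(rng, B, D) for _ in range(3))
        labels = rng.integers(0, 2, size=B) if labeled else None
        return ContrastiveBatch(h, ht, z, zt, zp, labels)

    def test_unlabeled_switching_rule(self):
        batch = self._batch(np.random.default_rng(3), labeled=False)
        total, bd = combined_loss(batch, LossConfig(), is_labeled=False)
        assert bd["lam"] == (0.5, 0.5, 0.0)
        assert float(total) == pytest.approx(
            0.5 * (bd["temporal"] + bd["channel"]), rel=1e-6)

    def test_labeled_equal_thirds(self):
        batch = self._batch(np.random.default_rng(4))
        total, bd = combined_loss(batch, LossConfig(), is_labeled=True)
        assert bd["lam"] == pytest.approx((1 / 3, 1 / 3, 1 / 3))
        assert float(total) == pytest.approx(
            (bd["temporal"] + bd["channel"] + bd["label"]) / 3, rel=1e-6)

    def test_label_term_uses_multiview_set_by_default(self):
        batch = self._batch(np.random.default_rng(5))
        _, bd = combined_loss(batch, LossConfig(), is_labeled=True)
        feats = np.concatenate([batch.z, batch.z_tilde])
        labs = np.concatenate([batch.labels, batch.labels])
        assert bd["label"] == pytest.approx(label_loss_ref(feats, labs, 0.1), rel=1e-6)
        _, bd_single = combined_loss(
            batch, LossConfig(label_loss_views="single"), is_labeled=True)
        assert bd_single["label"] == pytest.approx(
            label_loss_ref(batch.z, batch.labels, 0.1), rel=1e-6)

    def test_labeled_without_labels_rejected(self):
        batch = self._batch(np.random.default_rng(6), labeled=False)
        with pytest.raises(ValueError):
            combined_loss(batch, LossConfig(), is_labeled=True)

    def test_weights_must_be_convex(self):
        with pytest.raises(ValueError):
            LossWeights(0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            LossWeights(-0.2, 0.6, 0.6)


class TestGradients:
    def test_temporal_loss_differentiable_and_matches_numeric(self):
        rng = np.random.default_rng(8)
        h = rng.standard_normal((2, 3, 4))
        ht = rng.standard_normal((2, 3, 4))
        g = grad(lambda a: temporal_loss(a, ht, 1.0))(h)
        eps = 1e-6
        hp, hm = h.copy(), h.copy()
        hp[0, 1, 2] += eps
        hm[0, 1, 2] -= eps
        num = (float(temporal_loss(hp, ht, 1.0))
               - float(temporal_loss(hm, ht, 1.0))) / (2 * eps)
        assert g[0, 1, 2] == pytest.approx(num, rel=1e-4)
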