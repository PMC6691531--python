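"""Autoencoder unit tests: losses, schedule, sampling, gradients, training."""

import math

import numpy as np
import pytest

from batchbridge import (
    AEConfig,
    ClusterAssignment,
    ExpressionBatch,
    SimilarityMatrix,
    ValidationError,
    gaussian_preset,
    lambda_schedule,
    reconstruction_loss,
    sample_minibatch,
    total_loss,
    train,
    transfer_loss,
)
from batchbridge.mmd import mmd2
from batchbridge.model import TrainedModel, _MLP, _iteration_grads, embed


def _scaled_batches(n_cells=60, n_genes=8, n_clusters=2, seed=0):
    rng = np.random.default_rng(seed)
    batches, labels = [], {}
    for bid in ("Batch1", "Batch2"):
        centers = rng.uniform(0.2, 0.8, size=(n_clusters, n_genes))
        lab = rng.integers(1, n_clusters + 1, size=n_cells)
        X = np.clip(
            centers[lab - 1] + rng.normal(scale=0.05, size=(n_cells, n_genes)),
            0.0,
            1.0,
        )
        batches.append(
            ExpressionBatch(
                batch_id=bid,
                gene_ids=[f"g{i}" for i in range(n_genes)],
                cell_ids=[f"{bid}_c{i}" for i in range(n_cells)],
                values=X.T,
                stage="scaled",
            )
        )
        labels[bid] = lab
    return batches, ClusterAssignment(labels=labels)


def _full_mask(assignment):
    clusters = assignment.cluster_pairs()
    n = len(clusters)
    M = np.ones((n, n))
    batches = np.array([b for b, _ in clusters], dtype=object)
    M[batches[:, None] == batches[None, :]] = 0.0
    return SimilarityMatrix(clusters=clusters, values=M, stage="binary", s_thr=0.9)


def _empty_mask(assignment):
    clusters = assignment.cluster_pairs()
    M = np.zeros((len(clusters), len(clusters)))
    return SimilarityMatrix(clusters=clusters, values=M, stage="binary", s_thr=0.9)


class TestLambdaSchedule:
    def test_endpoints_and_midpoint(self):
        assert lambda_schedule(0, 100) == 0.0
        assert lambda_schedule(100, 100) == pytest.approx(
            2.0 / (1.0 + math.exp(-10.0)) - 1.0, abs=1e-12
        )
        assert lambda_schedule(50, 100) == pytest.approx(0.9866142981514305, abs=1e-7)

    def test_strictly_increasing_and_bounded(self):
        vals = [lambda_schedule(p, 200) for p in range(201)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[0] == 0.0 and vals[-1] < 1.0


class TestLosses:
    def test_reconstruction_examples(self):
        X = np.array([[0.0, 0.0]])
        assert reconstruction_loss(X, X) == 0.0
        assert reconstruction_loss(X, np.array([[1.0, 1.0]])) == 2.0
        Y = np.random.default_rng(0).random((4, 3))
        Yh = np.random.default_rng(1).random((4, 3))
        doubled = reconstruction_loss(np.vstack([Y, Y]), np.vstack([Yh, Yh]))
        assert doubled == pytest.approx(2 * reconstruction_loss(Y, Yh), rel=1e-12)

    def test_reconstruction_shape_mismatch(self):
        with pytest.raises(ValidationError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 2)))

    def test_total_loss(self):
        assert total_loss(1.0, 2.0, 0.5) == 2.0
        assert total_loss(3.0, 100.0, 0.0) == 3.0
        assert total_loss(3.0, 0.0, 0.7) == 3.0

    def test_transfer_loss_empty_single_and_additive(self):
        batches, assignment = _scaled_batches()
        rng = np.random.default_rng(0)
        blocks = {
            cl: rng.normal(size=(10, 2)) for cl in assignment.cluster_pairs()
        }
        assert transfer_loss(blocks, _empty_mask(assignment), [1.0]) == 0.0

        clusters = assignment.cluster_pairs()
        M = np.zeros((4, 4))
        i, j = 0, 2  # (Batch1,1) - (Batch2,1)
        M[i, j] = M[j, i] = 1.0
        single = SimilarityMatrix(clusters=clusters, values=M, stage="binary")
        expected = mmd2(blocks[clusters[i]], blocks[clusters[j]], [1.0])
        assert transfer_loss(blocks, single, [1.0]) == pytest.approx(
            expected, abs=1e-12
        )

        M2 = M.copy()
        M2[1, 3] = M2[3, 1] = 1.0
        double = SimilarityMatrix(clusters=clusters, values=M2, stage="binary")
        expected2 = expected + mmd2(blocks[clusters[1]], blocks[clusters[3]], [1.0])
        assert transfer_loss(blocks, double, [1.0]) == pytest.approx(
            expected2, abs=1e-12
        )


class TestMiniBatch:
    def test_size_formula(self):
        batches, assignment = _scaled_batches(n_cells=60, n_clusters=2)
        mb = sample_minibatch(batches, assignment, 50, np.random.default_rng(0))
        assert mb.B == 50 * 4
        mb1 = sample_minibatch(batches, assignment, 1, np.random.default_rng(0))
        assert mb1.B == 4

    def test_replacement_for_small_clusters(self):
        batches, assignment = _scaled_batches(n_cells=60, n_clusters=2)
        # each cluster has ~30 < 50 cells -> drawn with replacement
        mb = sample_minibatch(batches, assignment, 50, np.random.default_rng(0))
        block = mb.X[mb.blocks[("Batch1", 1)]]
        assert block.shape[0] == 50
        assert len(np.unique(block, axis=0)) < 50  # repeats present


class TestGradients:
    def test_iteration_gradient_matches_finite_differences(self):
        """Backprop through L1 + lambda*L2 agrees with numerical gradients."""
        batches, assignment = _scaled_batches(n_cells=20, n_genes=5)
        mask = _full_mask(assignment)
        config = AEConfig(
            hidden_sizes=(4, 2, 4), n_mb=5, kernel_bandwidths=[0.5, 1.0], seed=0
        )
        rng = np.random.default_rng(0)
        net = _MLP([5, 4, 2, 4, 5], rng)
        mb = sample_minibatch(batches, assignment, 5, rng)
        lam = 0.7

        def loss():
            acts = net.forward(mb.X)
            l1 = float(np.sum((acts[-1] - mb.X) ** 2))
            codes = acts[2]
            l2 = 0.0
            for (a, b) in mask.aligned_pairs():
                l2 += mmd2(codes[mb.blocks[a]], codes[mb.blocks[b]], [0.5, 1.0])
            return l1 + lam * l2

        gW, gb, l1, l2 = _iteration_grads(net, mb, mask, lam, 1, config)
        eps = 1e-6
        for l in range(net.n_layers):
            W = net.W[l]
            for idx in [(0, 0), (W.shape[0] - 1, W.shape[1] - 1)]:
                W[idx] += eps
                up = loss()
                W[idx] -= 2 * eps
                dn = loss()
                W[idx] += eps
                assert gW[l][idx] == pytest.approx(
                    (up - dn) / (2 * eps), rel=1e-4, abs=1e-6
                )
            b = net.b[l]
            b[0] += eps
            up = loss()
            b[0] -= 2 * eps
            dn = loss()
            b[0] += eps
            assert gb[l][0] == pytest.approx((up - dn) / (2 * eps), rel=1e-4, abs=1e-6)


class TestTraining:
    def test_plain_autoencoder_reduces_reconstruction(self):
        """With no aligned pairs the model is a plain autoencoder and learns."""
        batches, assignment = _scaled_batches(n_cells=40, n_genes=8)
        mask = _empty_mask(assignment)
        wins = 0
        for seed in range(3):
            cfg = AEConfig(hidden_sizes=(6, 2, 6), epochs=60, n_mb=10, seed=seed)
            model, _ = train(batches, assignment, mask, cfg)
            if model.history[-1]["L1"] < model.history[0]["L1"]:
                wins += 1
        assert wins >= 2

    def test_bottleneck_dimension_and_history(self):
        batches, assignment = _scaled_batches(n_cells=30, n_genes=8)
        cfg = gaussian_preset(epochs=5, n_mb=5, seed=1)
        model, emb = train(batches, assignment, _empty_mask(assignment), cfg)
        assert emb.dim == 2
        assert len(model.history) == 5
        assert emb.codes["Batch1"].shape == (30, 2)
        assert model.history[0]["lambda"] == pytest.approx(
            lambda_schedule(1, 5)
        )

    def test_training_reduces_aligned_mmd(self):
        """The transfer objective actually shrinks code-space MMD."""
        batches, assignment = _scaled_batches(n_cells=50, n_genes=8, seed=3)
        # shift batch 2 to create a batch effect
        b2 = batches[1]
        shifted = np.clip(b2.values + 0.15, 0.0, 1.0)
        batches[1] = b2.with_values(shifted, "scaled")
        mask_vals = np.zeros((4, 4))
        # align matching clusters only: (B1,1)-(B2,1), (B1,2)-(B2,2)
        mask_vals[0, 2] = mask_vals[2, 0] = 1.0
        mask_vals[1, 3] = mask_vals[3, 1] = 1.0
        mask = SimilarityMatrix(
            clusters=assignment.cluster_pairs(), values=mask_vals, stage="binary"
        )
        wins = 0
        for seed in range(3):
            cfg = AEConfig(hidden_sizes=(6, 2, 6), epochs=150, n_mb=20, seed=seed)
            model, emb = train(batches, assignment, mask, cfg)
            labels = assignment.labels
            before_model = TrainedModel(
                net=_MLP([8, 6, 2, 6, 8], np.random.default_rng(seed)),
                config=cfg,
                gene_ids=batches[0].gene_ids,
            )
            def pair_mmd(m):
                tot = 0.0
                for (a, ja), (b, jb) in [
                    (("Batch1", 1), ("Batch2", 1)),
                    (("Batch1", 2), ("Batch2", 2)),
                ]:
                    Za = embed(m, batches[0])[labels["Batch1"] == ja]
                    Zb = embed(m, batches[1])[labels["Batch2"] == jb]
                    tot += mmd2(Za, Zb)
                return tot
            if pair_mmd(model) < pair_mmd(before_model):
                wins += 1
        assert wins >= 2

    def test_embed_determinism_and_gene_check(self):
        batches, assignment = _scaled_batches(n_cells=30, n_genes=8)
        cfg = gaussian_preset(epochs=3, n_mb=5, seed=0)
        model, _ = train(batches, assignment, _empty_mask(assignment), cfg)
        Z1 = embed(model, batches[0])
        Z2 = embed(model, batches[0])
        np.testing.assert_array_equal(Z1, Z2)
        bad = batches[0].subset_genes(batches[0].gene_ids[:4])
        with pytest.raises(ValidationError):
            embed(model, bad)

    def test_encoder_is_the_documented_matrix_product(self):
        """Encoder of a hand-built linear model equals the explicit product."""
        cfg = AEConfig(hidden_sizes=(3, 2, 3), seed=0)
        net = _MLP([4, 3, 2, 3, 4], np.random.default_rng(0))
        # positive weights + positive input => leaky ReLU is the identity
        for l in range(net.n_layers):
            net.W[l] = np.abs(net.W[l])
            net.b[l] = np.zeros_like(net.b[l])
        model = TrainedModel(net=net, config=cfg, gene_ids=list("abcd"))
        X = np.abs(np.random.default_rng(1).normal(size=(6, 4)))
        expected = X @ net.W[0] @ net.W[1]
        assert np.allclose(model.encode(X), expected, atol=1e-10)

    def test_save_load_roundtrip(self, tmp_path):
        batches, assignment = _scaled_batches(n_cells=20, n_genes=6)
        cfg = AEConfig(hidden_sizes=(4, 2, 4), epochs=2, n_mb=5, seed=0)
        model, _ = train(batches, assignment, _empty_mask(assignment), cfg)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_allclose(
            embed(loaded, batches[0]), embed(model, batches[0]), atol=1e-12
        )
        assert loaded.config.hidden_sizes == [4, 2, 4]


def test_config_validation():
    with pytest.raises(ValidationError):
        AEConfig(hidden_sizes=(10, 10)).validate()
    with pytest.raises(ValidationError):
        AEConfig(epochs=0).validate()
    assert gaussian_preset().bottleneck_size == 2
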