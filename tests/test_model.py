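import math

import numpy as np
import pytest

from seqdsn.autograd import Tensor
from seqdsn.model import (DSNModel, LossWeights, ModelConfig,
                          classification_loss, difference_loss, init_model,
                          load_checkpoint, reconstruction_loss,
                          save_checkpoint, similarity_loss, total_loss)


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self):
        x = Tensor(np.random.default_rng(0).normal(size=(3, 5, 4)))
        assert reconstruction_loss(x, x, "mse").item() == 0.0
        assert reconstruction_loss(x, x, "simse").item() == 0.0

    def test_toy_values(self):
        # x all-ones 1x2, x_hat zeros: mse = 1; simse = 1 - 1 = 0
        x = Tensor(np.ones((1, 2)))
        xh = Tensor(np.zeros((1, 2)))
        assert reconstruction_loss(x, xh, "mse").item() == pytest.approx(1.0)
        assert reconstruction_loss(x, xh, "simse").item() == pytest.approx(0.0)

    def test_non_negative_random(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = Tensor(rng.normal(size=(4, 6)))
            xh = Tensor(rng.normal(size=(4, 6)))
            assert reconstruction_loss(x, xh, "mse").item() >= 0
            assert reconstruction_loss(x, xh, "simse").item() >= -1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            reconstruction_loss(Tensor(np.ones((2, 3))),
                                Tensor(np.ones((3, 2))))


class TestDifferenceLoss:
    def test_orthogonal_inputs_zero(self):
        # disjoint support -> exactly orthogonal columns
        h_c = Tensor(np.array([[1.0, 0, 0, 0], [0, 1.0, 0, 0]]))
        h_p = Tensor(np.array([[0, 0, 1.0, 0], [0, 0, 0, 1.0]]))
        assert difference_loss(h_c, h_p, center=False).item() == 0.0

    def test_single_sample_identity_is_one(self):
        # brute-force outer product: ||h h^T||_F^2 = ||h||^4 = 1
        h = np.array([[0.6, 0.8]])
        val = difference_loss(Tensor(h), Tensor(h), center=False).item()
        brute = np.linalg.norm(h.T @ h, "fro") ** 2
        assert val == pytest.approx(1.0)
        assert val == pytest.approx(brute)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(2)
        h_c = rng.normal(size=(6, 4))
        h_p = rng.normal(size=(6, 4))
        perm = rng.permutation(6)
        a = difference_loss(Tensor(h_c), Tensor(h_p)).item()
        b = difference_loss(Tensor(h_c[perm]), Tensor(h_p[perm])).item()
        assert a == pytest.approx(b, rel=1e-12)

    def test_batch_normalization_scale(self):
        rng = np.random.default_rng(3)
        h_c = rng.normal(size=(8, 4))
        h_p = rng.normal(size=(8, 4))
        raw = difference_loss(Tensor(h_c), Tensor(h_p),
                              batch_normalized=False).item()
        scaled = difference_loss(Tensor(h_c), Tensor(h_p)).item()
        assert scaled == pytest.approx(raw / 64)

    def test_zero_rows_stay_zero(self):
        h_c = Tensor(np.array([[0.0, 0.0], [1.0, 0.0]]))
        h_p = Tensor(np.array([[0.0, 0.0], [1.0, 0.0]]))
        val = difference_loss(h_c, h_p, center=False).item()
        assert np.isfinite(val)


class TestSimilarityLoss:
    def test_identical_samples_zero(self):
        rng = np.random.default_rng(4)
        h = rng.normal(size=(32, 4))
        val = similarity_loss(Tensor(h), Tensor(h.copy()), "mmd",
                              bandwidth=1.0).item()
        assert val == 0.0  # unbiased estimate clamped at zero

    def test_separated_clouds_large(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(64, 2)) + 5
        b = rng.normal(size=(64, 2)) - 5
        assert similarity_loss(Tensor(a), Tensor(b), "mmd").item() > 0.5

    def test_symmetry(self):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(16, 3))
        b = rng.normal(size=(16, 3)) + 1
        ab = similarity_loss(Tensor(a), Tensor(b), "mmd", bandwidth=2.0).item()
        ba = similarity_loss(Tensor(b), Tensor(a), "mmd", bandwidth=2.0).item()
        assert ab == pytest.approx(ba, rel=1e-10)

    def test_single_sample_batch_rejected(self):
        with pytest.raises(ValueError, match="larger batch"):
            similarity_loss(Tensor(np.ones((1, 3))), Tensor(np.ones((4, 3))),
                            "mmd", bandwidth=1.0)

    def test_dann_variant_trains_discriminator(self):
        cfg = ModelConfig(similarity_variant="dann")
        model = init_model(cfg, mode="source_only_classifier", seed=0)
        rng = np.random.default_rng(7)
        h_s = Tensor(rng.normal(size=(8, cfg.repr_dim)), requires_grad=True)
        h_t = Tensor(rng.normal(size=(8, cfg.repr_dim)), requires_grad=True)
        loss = similarity_loss(h_s, h_t, "dann",
                               discriminator=model.domain_discriminator)
        loss.backward()
        assert h_s.grad is not None  # reversed gradient reaches encoder side
        assert model.domain_discriminator.dense.weight.grad is not None


class TestClassificationLoss:
    def test_confident_correct_near_zero(self):
        logits = Tensor(np.array([[-30.0, 0.0], [0.0, -30.0]])).log_softmax(1)
        val = classification_loss(logits, [1, 0]).item()
        assert val == pytest.approx(0.0, abs=1e-10)

    def test_uniform_predictions_ln2(self):
        logits = Tensor(np.zeros((4, 2))).log_softmax(1)
        val = classification_loss(logits, [0, 1, 0, 1]).item()
        assert val == pytest.approx(math.log(2), abs=1e-12)

    def test_loss_decreases_with_better_logit(self):
        z = np.array([[0.3, 0.1]])
        base = classification_loss(Tensor(z).log_softmax(1), [0]).item()
        z2 = z.copy()
        z2[0, 0] += 0.1
        better = classification_loss(Tensor(z2).log_softmax(1), [0]).item()
        assert better < base

    def test_bad_labels_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            classification_loss(Tensor(np.zeros((1, 2))), [2])


class TestTotalLoss:
    def test_unit_parts_with_default_weights(self):
        total, breakdown = total_loss(1.0, 1.0, 1.0, 1.0, 1.0,
                                      LossWeights(), mode="dual_classifier")
        assert total.item() == pytest.approx(2.345)
        assert breakdown.total == pytest.approx(
            0.02 * breakdown.recon + 0.075 * breakdown.difference
            + 0.25 * breakdown.similarity + breakdown.source_cls
            + 1.0 * breakdown.target_cls)

    def test_zero_weights_and_losses(self):
        total, _ = total_loss(5.0, 5.0, 5.0, 0.0, None,
                              LossWeights(0, 0, 0, 0),
                              mode="source_only_classifier")
        assert total.item() == 0.0

    def test_mode1_drops_target_term(self):
        t1, _ = total_loss(1, 1, 1, 1, None, mode="source_only_classifier")
        t2, _ = total_loss(1, 1, 1, 1, 1.0, mode="dual_classifier")
        assert t2.item() - t1.item() == pytest.approx(1.0)

    def test_dual_mode_requires_target_loss(self):
        with pytest.raises(ValueError, match="target"):
            total_loss(1, 1, 1, 1, None, mode="dual_classifier")

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            LossWeights(alpha=-0.1)


class TestDSNModel:
    def test_same_seed_identical_parameters(self):
        a = init_model(ModelConfig(), seed=3)
        b = init_model(ModelConfig(), seed=3)
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)

    def test_forward_shapes(self):
        cfg = ModelConfig(window_length=21)
        model = init_model(cfg, mode="dual_classifier", seed=0)
        rng = np.random.default_rng(0)
        x_s = Tensor(np.eye(4)[rng.integers(0, 4, (3, 21))])
        x_t = Tensor(np.eye(4)[rng.integers(0, 4, (3, 21))])
        out = model(x_s, x_t)
        assert out.h_c_source.shape == (3, cfg.repr_dim)
        assert out.h_p_target.shape == (3, cfg.repr_dim)
        assert out.recon_source.shape == (3, 21, 4)
        assert out.source_logits.shape == (3, 2)
        assert out.target_logits.shape == (3, 2)

    def test_mode1_has_no_target_classifier(self):
        model = init_model(ModelConfig(), mode="source_only_classifier")
        assert model.target_classifier is None
        with pytest.raises(ValueError, match="no target classifier"):
            model.predict_scores(np.zeros((1, 41, 4)), classifier="target")

    def test_gradient_flow_contract(self):
        """difference reaches shared+private; similarity & classification
        reach only the shared path."""
        model = init_model(ModelConfig(window_length=15), seed=1)
        rng = np.random.default_rng(1)
        x_s = Tensor(np.eye(4)[rng.integers(0, 4, (6, 15))])
        x_t = Tensor(np.eye(4)[rng.integers(0, 4, (6, 15))])

        def grads(loss_of_out):
            model.zero_grad()
            out = model(x_s, x_t)
            loss_of_out(out).backward()
            shared = any(p.grad is not None and np.abs(p.grad).sum() > 0
                         for p in model.shared_encoder.parameters())
            private = any(p.grad is not None and np.abs(p.grad).sum() > 0
                          for p in model.private_source_encoder.parameters())
            clf = any(p.grad is not None and np.abs(p.grad).sum() > 0
                      for p in model.source_classifier.parameters())
            return shared, private, clf

        s, p, c = grads(lambda o: difference_loss(o.h_c_source, o.h_p_source))
        assert s and p and not c
        s, p, c = grads(lambda o: similarity_loss(o.h_c_source, o.h_c_target,
                                                  "mmd", bandwidth=4.0))
        assert s and not p and not c
        s, p, c = grads(lambda o: classification_loss(o.source_logits,
                                                      np.zeros(6, int)))
        assert s and not p and c

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_filters=0)
        with pytest.raises(ValueError):
            ModelConfig(recon_variant="huber")
        with pytest.raises(ValueError, match="mode"):
            init_model(ModelConfig(), mode="mode3")

    def test_checkpoint_roundtrip(self, tmp_path):
        model = init_model(ModelConfig(window_length=15), seed=4)
        model.eval()
        rng = np.random.default_rng(2)
        x = np.eye(4)[rng.integers(0, 4, (5, 15))]
        scores = model.predict_scores(x, classifier="source")
        save_checkpoint(model, tmp_path / "ck.npz")
        loaded = load_checkpoint(tmp_path / "ck.npz")
        loaded.eval()
        np.testing.assert_allclose(
            loaded.predict_scores(x, classifier="source"), scores)
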