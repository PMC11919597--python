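"""Capsule operations: squash, prediction vectors, routing, losses, model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from capm7g import (
    CapsuleNet,
    CapsuleNetConfig,
    CnnMlpBaseline,
    dynamic_routing,
    load_checkpoint,
    margin_loss,
    predict_vectors,
    reconstruction_loss,
    save_checkpoint,
    squash,
    total_loss,
)
from capm7g.autodiff import Tensor
from capm7g.capsnet import make_optimizer


# --------------------------------------------------------------------------
# independent routing oracle: scalar-loop transcription of the
# routing-by-agreement pseudocode, sharing no code with the implementation
# --------------------------------------------------------------------------


def oracle_squash(s):
    n = np.linalg.norm(s)
    if n == 0:
        return np.zeros_like(s)
    return (n**2 / (1 + n**2)) * (s / n)


def oracle_routing(u_hat, iterations):
    L, J, D = u_hat.shape
    b = np.zeros((L, J))
    for it in range(iterations):
        c = np.empty((L, J))
        for i in range(L):
            e = np.exp(b[i] - b[i].max())
            c[i] = e / e.sum()
        S = np.zeros((J, D))
        for j in range(J):
            for i in range(L):
                S[j] += c[i, j] * u_hat[i, j]
        v = np.array([oracle_squash(S[j]) for j in range(J)])
        if it < iterations - 1:
            for i in range(L):
                for j in range(J):
                    b[i, j] += float(u_hat[i, j] @ v[j])
    return b, c, S, v


class TestSquash:
    def test_zero_maps_to_zero_without_nan(self):
        out = squash(np.zeros(8)).data
        assert np.all(out == 0) and np.all(np.isfinite(out))

    def test_unit_vector_halves(self):
        e = np.zeros(5)
        e[0] = 1.0
        out = squash(e).data
        assert abs(np.linalg.norm(out) - 0.5) < 1e-9

    def test_huge_vector_saturates_below_one(self):
        out = squash(1000.0 * np.ones(4) / 2.0).data
        n = np.linalg.norm(out)
        assert 0.999999 < n < 1.0

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=16),
           st.floats(1e-6, 1e3))
    def test_direction_preserved_and_norm_bounded(self, vec, scale):
        s = np.array(vec)
        if np.linalg.norm(s) == 0:
            return
        s = s / np.linalg.norm(s) * scale
        out = squash(s).data
        assert np.linalg.norm(out) < 1.0
        cos = s @ out / (np.linalg.norm(s) * np.linalg.norm(out))
        assert cos == pytest.approx(1.0, abs=1e-9)


class TestPredictVectors:
    def test_identity_weights_pass_through(self):
        u = np.zeros((1, 2, 3))
        u[0, :, 0] = 1.0  # e1 for both capsules
        W = np.broadcast_to(np.eye(3), (2, 2, 3, 3)).copy()
        out = predict_vectors(u, W).data
        np.testing.assert_allclose(out, np.broadcast_to(u[:, :, None, :], out.shape))

    def test_zero_weights_give_zero(self):
        u = np.random.default_rng(0).standard_normal((1, 4, 8))
        out = predict_vectors(u, np.zeros((4, 2, 8, 16))).data
        assert np.all(out == 0)

    def test_random_case_matches_explicit_products(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal((2, 2))  # L=2, m=2
        W = rng.standard_normal((2, 2, 2, 3))
        out = predict_vectors(u, W).data[0]
        for i in range(2):
            for j in range(2):
                np.testing.assert_allclose(out[i, j], u[i] @ W[i, j], atol=1e-12)

    def test_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            predict_vectors(np.zeros((1, 3, 8)), np.zeros((4, 2, 8, 16)))


class TestDynamicRouting:
    def test_single_primary_capsule_splits_evenly(self):
        u_hat = np.random.default_rng(2).standard_normal((1, 1, 2, 4))
        v, state = dynamic_routing(u_hat, iterations=1)
        np.testing.assert_allclose(state.couplings, 0.5)
        for j in range(2):
            np.testing.assert_allclose(
                v.data[0, j], oracle_squash(0.5 * u_hat[0, 0, j]), atol=1e-9
            )

    def test_identical_predictions_keep_symmetric_couplings(self):
        base = np.random.default_rng(3).standard_normal((1, 5, 1, 4))
        u_hat = np.repeat(base, 2, axis=2)  # same prediction for both classes
        _, state = dynamic_routing(u_hat, iterations=4)
        np.testing.assert_allclose(state.couplings, 0.5, atol=1e-12)

    @pytest.mark.parametrize("L,r", [(3, 3), (1, 1), (5, 2), (8, 5)])
    def test_matches_scalar_oracle(self, L, r):
        rng = np.random.default_rng(L * 10 + r)
        u_hat = rng.standard_normal((L, 2, 6))
        v, state = dynamic_routing(u_hat, iterations=r)
        b, c, S, vo = oracle_routing(u_hat, r)
        np.testing.assert_allclose(state.logits[0], b, atol=1e-6)
        np.testing.assert_allclose(state.couplings[0], c, atol=1e-6)
        np.testing.assert_allclose(state.weighted_sums[0], S, atol=1e-6)
        np.testing.assert_allclose(v.data[0], vo, atol=1e-6)

    def test_couplings_always_normalized(self):
        rng = np.random.default_rng(9)
        for r in (1, 2, 5):
            u_hat = rng.standard_normal((2, 6, 2, 4))
            _, state = dynamic_routing(u_hat, iterations=r)
            np.testing.assert_allclose(state.couplings.sum(axis=2), 1.0, atol=1e-9)
            assert np.all(state.couplings >= 0)

    def test_requires_at_least_one_iteration(self):
        with pytest.raises(ValueError):
            dynamic_routing(np.zeros((1, 2, 4)), iterations=0)


class TestLosses:
    @pytest.mark.parametrize(
        "p_true,p_false,expected",
        [
            (0.9, 0.1, 0.0),
            (0.0, 0.0, 0.81),
            (0.5, 0.6, 0.16 + 0.5 * 0.25),
        ],
    )
    def test_margin_loss_hand_cases(self, p_true, p_false, expected):
        probs = np.array([[p_false, p_true]])
        onehot = np.array([[0.0, 1.0]])
        assert float(margin_loss(probs, onehot).data) == pytest.approx(
            expected, abs=1e-9
        )

    def test_margin_loss_batch_mean(self):
        probs = np.array([[0.1, 0.9], [0.0, 0.0]])
        onehot = np.array([[0.0, 1.0], [0.0, 1.0]])
        assert float(margin_loss(probs, onehot).data) == pytest.approx(0.405, abs=1e-9)

    def test_reconstruction_identical_is_zero(self):
        img = np.random.default_rng(0).random((3, 4, 4))
        assert float(reconstruction_loss(img, Tensor(img)).data) == 0.0

    def test_reconstruction_all_ones_vs_zeros(self):
        a = np.zeros((1, 2, 2))
        assert float(reconstruction_loss(a, Tensor(np.ones((1, 2, 2)))).data) == 1.0

    def test_reconstruction_toy_mse(self):
        orig = np.array([[[0.0, 0.5], [1.0, 0.25]]])
        recon = np.array([[[0.1, 0.5], [0.8, 0.5]]])
        expected = (0.01 + 0.0 + 0.04 + 0.0625) / 4
        assert float(reconstruction_loss(orig, Tensor(recon)).data) == pytest.approx(
            expected, abs=1e-12
        )

    def test_reconstruction_shape_mismatch_is_error(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((1, 2, 2)), Tensor(np.zeros((1, 3, 3))))

    @pytest.mark.parametrize(
        "margin,recon,alpha,n,expected",
        [
            (1.0, 0.7, 0.0, 4096, 1.0),
            (1.0, 0.0, 0.0005, 4096, 1.0),
            (0.5, 0.1, 0.0005, 4096, 0.5 + 0.2048),
        ],
    )
    def test_total_loss_weighting(self, margin, recon, alpha, n, expected):
        assert float(total_loss(margin, recon, alpha, n).data) == pytest.approx(
            expected, abs=1e-12
        )


@pytest.fixture(scope="module")
def net_and_images():
    cfg = CapsuleNetConfig.tiny(seed=5)
    net = CapsuleNet(cfg)
    images = np.random.default_rng(6).random((4, 16, 16))
    return cfg, net, images


class TestCapsuleNetForward:
    def test_output_contracts(self, net_and_images):
        cfg, net, images = net_and_images
        out = net.forward(images)
        assert out.probabilities.shape == (4, cfg.num_digit_capsules)
        assert np.all(out.probabilities.data >= 0)
        assert np.all(out.probabilities.data < 1)
        assert out.reconstruction.shape == (4, 16, 16)
        assert np.all((out.reconstruction.data >= 0) & (out.reconstruction.data <= 1))
        assert out.digit_vectors.shape == (4, 2, cfg.digit_capsule_dim)
        np.testing.assert_array_equal(
            out.chosen_class, out.probabilities.data.argmax(axis=1)
        )
        # probability is exactly the capsule norm
        np.testing.assert_allclose(
            out.probabilities.data,
            np.linalg.norm(out.digit_vectors.data, axis=-1),
            atol=1e-9,
        )

    def test_identical_inputs_identical_outputs(self, net_and_images):
        _, net, images = net_and_images
        a = net.forward(images[:1]).probabilities.data
        b = net.forward(images[:1]).probabilities.data
        np.testing.assert_array_equal(a, b)

    def test_zero_and_dense_images_activate_differently(self, net_and_images):
        _, net, images = net_and_images
        zero = net.forward(np.zeros((1, 16, 16)))
        dense = net.forward(images[:1])
        assert not np.allclose(zero.primary, dense.primary)

    def test_wrong_image_size_is_error(self, net_and_images):
        _, net, _ = net_and_images
        with pytest.raises(ValueError):
            net.forward(np.zeros((1, 8, 8)))

    def test_seeded_construction_is_reproducible(self):
        a = CapsuleNet(CapsuleNetConfig.tiny(seed=11))
        b = CapsuleNet(CapsuleNetConfig.tiny(seed=11))
        x = np.random.default_rng(1).random((2, 16, 16))
        np.testing.assert_array_equal(
            a.forward(x).probabilities.data, b.forward(x).probabilities.data
        )


class TestTrainingDynamics:
    def test_loss_decreases_on_fixed_batch(self):
        """Overfit smoke test: 20 Adam steps on 8 samples reduce the loss."""
        net = CapsuleNet(CapsuleNetConfig.tiny(seed=7))
        rng = np.random.default_rng(8)
        x = rng.random((8, 16, 16))
        y = np.array([0, 1] * 4)
        opt = make_optimizer(net, lr=0.01)
        first = None
        for step in range(20):
            opt.zero_grad()
            loss, _ = net.loss(x, y)
            if step == 0:
                first = float(loss.data)
            loss.backward()
            opt.step()
        final, _ = net.loss(x, y)
        assert float(final.data) < first

    def test_alpha_zero_ignores_decoder_weights(self):
        """Without reconstruction the loss is independent of the decoder."""
        net = CapsuleNet(CapsuleNetConfig.tiny(seed=9))
        x = np.random.default_rng(10).random((3, 16, 16))
        y = np.array([0, 1, 0])
        base, _ = net.loss(x, y, use_reconstruction=False)
        net.dec2_w.data += 100.0
        perturbed, _ = net.loss(x, y, use_reconstruction=False)
        assert float(base.data) == float(perturbed.data)
        # and the decoder receives no gradient
        perturbed.backward()
        assert net.dec2_w.grad is None or np.all(net.dec2_w.grad == 0)


class TestConfigAndCheckpoints:
    def test_invalid_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            CapsuleNetConfig(margin_upper=0.1, margin_lower=0.9)
        with pytest.raises(ValueError):
            CapsuleNetConfig(routing_iterations=0)
        with pytest.raises(ValueError):
            CapsuleNetConfig(conv_channels=(8, 30))  # not divisible by m=8

    def test_primary_capsule_count_follows_geometry(self):
        cfg = CapsuleNetConfig.tiny()
        ho, wo = cfg.conv_geometry()[-1]
        assert cfg.num_primary_capsules == (
            cfg.conv_channels[1] // cfg.primary_capsule_dim
        ) * ho * wo

    def test_checkpoint_roundtrip(self, tmp_path):
        net = CapsuleNet(CapsuleNetConfig.tiny(seed=12))
        p = tmp_path / "m.ckpt"
        save_checkpoint(net, p, extra={"encoder_mode": "fcgr", "window_length": 101})
        model, extra = load_checkpoint(p)
        assert extra["window_length"] == 101
        x = np.random.default_rng(0).random((2, 16, 16))
        np.testing.assert_array_equal(
            net.forward(x).probabilities.data, model.forward(x).probabilities.data
        )

    def test_baseline_checkpoint_roundtrip(self, tmp_path):
        net = CnnMlpBaseline(CapsuleNetConfig.tiny(seed=13))
        p = tmp_path / "b.ckpt"
        save_checkpoint(net, p)
        model, _ = load_checkpoint(p)
        assert isinstance(model, CnnMlpBaseline)

    def test_corrupt_version_rejected(self, tmp_path):
        import io, json

        net = CapsuleNet(CapsuleNetConfig.tiny())
        p = tmp_path / "m.ckpt"
        save_checkpoint(net, p)
        data = np.load(p)
        meta = json.loads(bytes(data["meta"]).decode())
        meta["format_version"] = "bogus"
        buf = io.BytesIO()
        arrays = {k: data[k] for k in data.files if k != "meta"}
        np.savez(buf, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)
        p.write_bytes(buf.getvalue())
        with pytest.raises(ValueError, match="format"):
            load_checkpoint(p)
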