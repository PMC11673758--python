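"""Multistream recurrent ConvNet: contracts, freezing, initialisation, gradients."""

import numpy as np
import pytest

from conftest import random_batch
from groomkit.msrc_model import (
    MSRCConfig,
    build_model,
    init_temporal_from_rgb,
    load_checkpoint,
    save_checkpoint,
)
from groomkit.nn import softmax, softmax_cross_entropy
from groomkit.nn.optim import Adam


@pytest.fixture(scope="module")
def tiny_model():
    return build_model(MSRCConfig(seed=1))


@pytest.fixture(scope="module")
def trained_on_eight():
    """A tiny model overfitted on 8 linearly separable synthetic clips.

    Class 1 has strong constant flow and a segment-dependent ramp; class 0 is
    near-static.  Also serves the 200-step overfitting sanity property.
    """
    cfg = MSRCConfig(input_size=(16, 16), temporal_in_channels=4, seed=2)
    model = build_model(cfg)
    rng = np.random.default_rng(2)
    images = rng.uniform(0, 1, (8, 3, 3, 16, 16))
    fx = np.zeros((8, 3, 4, 16, 16))
    fy = np.zeros((8, 3, 4, 16, 16))
    labels = np.array([0, 1] * 4)
    for i in range(8):
        if labels[i] == 1:
            for seg in range(3):
                fx[i, seg] = 0.5 + 0.1 * seg  # segment-ordered motion ramp
            fy[i] = 0.3
        else:
            fx[i] = rng.normal(0, 0.02, fx[i].shape)
    opt = Adam(model.params(), lr=5e-3)
    steps = 0
    for step in range(200):
        logits = model.forward(images, fx, fy, train=True)
        loss, dlogits = softmax_cross_entropy(logits, labels)
        acc = (logits.argmax(1) == labels).mean()
        steps = step + 1
        if acc == 1.0 and loss < 0.1:
            break
        opt.zero_grad()
        model.backward(dlogits)
        opt.step()
    return model, (images, fx, fy), labels, steps


class TestForwardContract:
    def test_scores_softmax_to_one(self, tiny_model):
        rng = np.random.default_rng(0)
        imgs, fx, fy = random_batch(rng, b=4)
        scores = tiny_model.forward(imgs, fx, fy, train=False)
        assert scores.shape == (4, 2)
        probs = softmax(scores)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_eval_mode_deterministic(self, tiny_model):
        rng = np.random.default_rng(1)
        imgs, fx, fy = random_batch(rng)
        a = tiny_model.forward(imgs, fx, fy, train=False)
        b = tiny_model.forward(imgs, fx, fy, train=False)
        np.testing.assert_array_equal(a, b)

    def test_duplicate_sample_rows_identical(self, tiny_model):
        rng = np.random.default_rng(2)
        imgs, fx, fy = random_batch(rng, b=1)
        imgs2 = np.concatenate([imgs, imgs])
        fx2 = np.concatenate([fx, fx])
        fy2 = np.concatenate([fy, fy])
        out = tiny_model.forward(imgs2, fx2, fy2, train=False)
        np.testing.assert_allclose(out[0], out[1], atol=1e-12)

    def test_shape_errors_name_the_stream(self, tiny_model):
        rng = np.random.default_rng(3)
        imgs, fx, fy = random_batch(rng)
        with pytest.raises(ValueError, match="spatial"):
            tiny_model.forward(imgs[:, :, :2], fx, fy)
        with pytest.raises(ValueError, match="temporal_x"):
            tiny_model.forward(imgs, fx[:, :, :5], fy)
        with pytest.raises(ValueError, match="temporal_y"):
            tiny_model.forward(imgs, fx, fy[:, :, :5])

    def test_temporal_stream_accepts_ten_channel_stacks(self, tiny_model):
        # Nf = 10 flow fields per segment is the default temporal input depth
        assert tiny_model.config.temporal_in_channels == 10
        rng = np.random.default_rng(4)
        imgs, fx, fy = random_batch(rng, nf=10)
        assert tiny_model.forward(imgs, fx, fy).shape == (2, 2)


class TestBackboneRegistry:
    def test_tiny_backbone_builds_offline(self):
        model = build_model(MSRCConfig(backbone="tiny_test_cnn", seed=0))
        assert len(model.params()) > 0

    def test_resnet50_unavailable_with_clear_error(self):
        with pytest.raises(ValueError, match="resnet50"):
            build_model(MSRCConfig(backbone="resnet50", seed=0))

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ValueError, match="backbone"):
            MSRCConfig(backbone="vgg16")

    def test_shared_temporal_weights_mode(self):
        model = build_model(MSRCConfig(share_temporal_weights=True, seed=5))
        assert model.temporal_cnn_y is model.temporal_cnn_x
        rng = np.random.default_rng(5)
        imgs, fx, fy = random_batch(rng)
        logits = model.forward(imgs, fx, fy, train=True)
        _, dlogits = softmax_cross_entropy(logits, np.array([0, 1]))
        model.backward(dlogits)  # caches must survive the shared pass


class TestFreezing:
    def test_frozen_gradients_identically_zero(self):
        model = build_model(MSRCConfig(finetune_scope="last_block", seed=6))
        frozen = model.frozen_params()
        assert frozen, "finetune scope should freeze the early conv blocks"
        frozen_names = {p.name for p in frozen}
        assert any("block1" in n for n in frozen_names)
        assert not any("block3" in n for n in frozen_names)
        rng = np.random.default_rng(6)
        imgs, fx, fy = random_batch(rng)
        logits = model.forward(imgs, fx, fy, train=True)
        _, dlogits = softmax_cross_entropy(logits, np.array([1, 0]))
        for p in model.params():
            p.zero_grad()
        model.backward(dlogits)
        for p in frozen:
            assert np.all(p.grad == 0.0)
        # trainable parameters must receive gradient signal
        live = [p for p in model.params() if p.trainable]
        assert any(np.any(p.grad != 0) for p in live)

    def test_adam_never_updates_frozen_params(self):
        model = build_model(MSRCConfig(finetune_scope="last_block", seed=7))
        before = {p.name: p.value.copy() for p in model.frozen_params()}
        rng = np.random.default_rng(7)
        imgs, fx, fy = random_batch(rng)
        opt = Adam(model.params(), lr=1e-2)
        logits = model.forward(imgs, fx, fy, train=True)
        _, dlogits = softmax_cross_entropy(logits, np.array([1, 0]))
        opt.zero_grad()
        model.backward(dlogits)
        opt.step()
        for p in model.frozen_params():
            np.testing.assert_array_equal(p.value, before[p.name])


class TestTemporalInit:
    def test_constant_kernels_scaled_by_three_over_nf(self):
        k = np.full((4, 3, 3, 3), 2.0)
        out = init_temporal_from_rgb(k, n_flow=10)
        assert out.shape == (4, 10, 3, 3)
        np.testing.assert_allclose(out, 2.0 * 3.0 / 10.0)

    def test_random_kernels_match_channel_mean_oracle(self):
        rng = np.random.default_rng(8)
        k = rng.normal(size=(6, 3, 5, 5))
        out = init_temporal_from_rgb(k, n_flow=7)
        oracle = np.stack([k[f].mean(axis=0) for f in range(6)])
        for c in range(7):
            np.testing.assert_allclose(out[:, c], oracle * 3.0 / 7.0)

    def test_nf_three_preserves_mean_exactly(self):
        rng = np.random.default_rng(9)
        k = rng.normal(size=(2, 3, 3, 3))
        out = init_temporal_from_rgb(k, n_flow=3)
        np.testing.assert_allclose(out[:, 0], k.mean(axis=1))

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match="3"):
            init_temporal_from_rgb(np.zeros((4, 5, 3, 3)), n_flow=10)


class TestTrainedTinyModel:
    def test_overfits_eight_separable_clips_within_200_steps(self, trained_on_eight):
        model, (images, fx, fy), labels, steps = trained_on_eight
        assert steps <= 200
        preds = model.forward(images, fx, fy, train=True).argmax(1)
        np.testing.assert_array_equal(preds, labels)

    def test_segment_order_sensitivity(self, trained_on_eight):
        # the LSTM consumes segments in order; permuting them changes the score
        model, (images, fx, fy), labels, _ = trained_on_eight
        i = int(np.flatnonzero(labels == 1)[0])
        base = model.forward(images[i : i + 1], fx[i : i + 1], fy[i : i + 1],
                             train=False)
        perm = [2, 0, 1]
        out = model.forward(images[i : i + 1, perm], fx[i : i + 1, perm],
                            fy[i : i + 1, perm], train=False)
        assert np.abs(base - out).max() > 1e-6


class TestGradientsAndCheckpoints:
    def test_analytic_gradients_match_finite_differences(self):
        cfg = MSRCConfig(input_size=(8, 8), temporal_in_channels=4, seed=3)
        model = build_model(cfg)
        rng = np.random.default_rng(0)
        imgs = rng.normal(size=(3, 3, 3, 8, 8))
        fx = rng.normal(size=(3, 3, 4, 8, 8))
        fy = rng.normal(size=(3, 3, 4, 8, 8))
        y = np.array([0, 1, 1])

        def loss_value():
            return softmax_cross_entropy(model.forward(imgs, fx, fy, train=True), y)[0]

        for p in model.params():
            p.zero_grad()
        loss, dl = softmax_cross_entropy(model.forward(imgs, fx, fy, train=True), y)
        model.backward(dl)
        eps = 1e-6
        probe = np.random.default_rng(1)
        for p in model.params():
            flat, gflat = p.value.ravel(), p.grad.ravel()
            for _ in range(3):
                i = probe.integers(flat.size)
                old = flat[i]
                flat[i] = old + eps
                lp = loss_value()
                flat[i] = old - eps
                lm = loss_value()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                denom = max(1e-8, abs(num) + abs(gflat[i]))
                assert abs(num - gflat[i]) / denom < 1e-4, p.name

    def test_checkpoint_roundtrip_preserves_outputs(self, tiny_model, tmp_path):
        path = tmp_path / "model.npz"
        save_checkpoint(tiny_model, path, extra={"seed": 1})
        clone = load_checkpoint(path)
        rng = np.random.default_rng(10)
        imgs, fx, fy = random_batch(rng)
        np.testing.assert_array_equal(
            tiny_model.forward(imgs, fx, fy, train=False),
            clone.forward(imgs, fx, fy, train=False),
        )
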