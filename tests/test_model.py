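"""U-Net forward/backward correctness, losses, training behavior."""

import numpy as np
import pytest

from octasv.model import (
    ModelSpec,
    TrainConfig,
    UNet,
    build_model,
    load_model,
    mse_loss,
    predict_volume,
    save_model,
    ssim_loss,
    train,
)


class TestForwardContract:
    def test_output_shape(self, rng):
        m = build_model(ModelSpec(in_channels=3))
        y = m.forward(rng.random((2, 3, 64, 64)).astype(np.float32))
        assert y.shape == (2, 1, 64, 64)
        assert np.all((y > 0) & (y < 1))

    def test_indivisible_size_rejected(self, rng):
        m = build_model(ModelSpec(in_channels=1, depth=3))
        with pytest.raises(ValueError):
            m.forward(rng.random((1, 1, 30, 30)))

    def test_width_doubling_quadruples_conv_params(self):
        p16 = build_model(ModelSpec(base_width=16)).n_params
        p32 = build_model(ModelSpec(base_width=32)).n_params
        assert p32 / p16 == pytest.approx(4.0, abs=0.05)

    def test_zeroed_model_constant_output(self, rng):
        m = build_model(ModelSpec(in_channels=1))
        for c in m.convs:
            c.W[:] = 0
            c.b[:] = 0
        y = m.forward(rng.random((1, 1, 32, 32)).astype(np.float32))
        assert np.allclose(y, 0.5)

    def test_translation_consistency_pool_aligned(self, rng):
        # shift by a multiple of the full pooling stride and compare the
        # interior beyond the network's receptive-field halo
        m = build_model(ModelSpec(in_channels=3), seed=1)
        x = rng.random((1, 3, 128, 128)).astype(np.float32)
        y1 = m.forward(x)
        y2 = m.forward(np.roll(x, 8, axis=3))
        interior = np.abs(np.roll(y1, 8, axis=3) - y2)[0, 0, 32:96, 40:96]
        assert interior.max() < 1e-3


class TestGradients:
    @pytest.mark.parametrize("loss_fn", [mse_loss, ssim_loss])
    def test_backward_matches_finite_differences(self, rng, loss_fn):
        m = build_model(ModelSpec(in_channels=3, base_width=2, depth=2), seed=1)
        x = rng.random((2, 3, 16, 16)).astype(np.float32)
        t = rng.random((2, 1, 16, 16)).astype(np.float32)
        pred = m.forward(x)
        _, dpred = loss_fn(pred, t)
        m.zero_grad()
        m.backward(dpred)
        conv = m.convs[0]
        for idx in [(0, 0, 0, 0), (1, 1, 2, 1)]:
            eps = 1e-3
            orig = float(conv.W[idx])
            conv.W[idx] = orig + eps
            lp = loss_fn(m.forward(x), t)[0]
            conv.W[idx] = orig - eps
            lm = loss_fn(m.forward(x), t)[0]
            conv.W[idx] = orig
            numeric = (lp - lm) / (2 * eps)
            assert conv.dW[idx] == pytest.approx(numeric, rel=0.08, abs=1e-6)


class TestLosses:
    def test_mse_zero_iff_identical(self, rng):
        p = rng.random((1, 1, 16, 16))
        assert mse_loss(p, p.copy())[0] == 0.0
        assert mse_loss(p, p + 0.1)[0] > 0

    def test_ssim_loss_zero_on_identical(self, rng):
        p = rng.random((32, 32))
        loss, grad = ssim_loss(p, p.copy())
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_ssim_loss_bounded(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            loss, _ = ssim_loss(r.random((32, 32)), r.random((32, 32)))
            assert 0.0 <= loss <= 2.0

    def test_ssim_loss_consistent_with_metric(self, rng):
        from octasv.metrics import ssim_map

        a, b = rng.random((64, 64)), rng.random((64, 64))
        loss, _ = ssim_loss(a, b)
        assert loss == pytest.approx(1.0 - ssim_map(a, b, L=1.0)[0], abs=1e-6)


class TestTraining:
    def _toy_data(self, rng, n=4):
        x = rng.random((n, 1, 32, 32))
        y = np.clip(x * 0.5, 0, 1)  # learnable pixelwise map
        return x, y

    def test_one_sample_overfit(self, rng):
        x, y = self._toy_data(rng, n=1)
        m = build_model(ModelSpec(in_channels=1), seed=0)
        hist = train(m, x, y, TrainConfig(loss="mse", epochs=200, batch=1, seed=0))
        assert hist["train_loss"][-1] < 0.1 * hist["train_loss"][0]

    def test_loss_curve_decreases_after_smoothing(self, rng):
        x, y = self._toy_data(rng, n=8)
        m = build_model(ModelSpec(in_channels=1, base_width=8), seed=0)
        hist = train(m, x, y, TrainConfig(loss="mse", epochs=30, batch=4, seed=0))
        smooth = np.convolve(hist["train_loss"], np.ones(5) / 5, mode="valid")
        assert smooth[-1] <= smooth[0]

    def test_seeded_training_is_bitwise_deterministic(self, rng):
        x, y = self._toy_data(rng)
        h = []
        for _ in range(2):
            m = build_model(ModelSpec(in_channels=1, base_width=4), seed=2)
            h.append(train(m, x, y, TrainConfig(epochs=2, seed=3))["train_loss"])
        assert h[0] == h[1]

    def test_empty_dataset_rejected(self):
        m = build_model(ModelSpec(in_channels=1))
        with pytest.raises(ValueError):
            train(m, np.empty((0, 1, 32, 32)), np.empty((0, 1, 32, 32)), TrainConfig())


class TestPredictVolume:
    def test_shape_and_provenance(self, small_phantom):
        _, vol, _ = small_phantom
        m = build_model(ModelSpec(in_channels=3), seed=0)
        out = predict_volume(m, vol)
        assert out.data.shape == (vol.S, vol.Z, vol.X)
        assert out.provenance == "model"
        assert np.all(out.data >= 0)

    def test_channel_count_follows_spec(self, small_phantom):
        _, vol, _ = small_phantom
        m1 = build_model(ModelSpec(in_channels=1), seed=0)
        out = predict_volume(m1, vol)
        assert out.n_scans == 1

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        m = build_model(ModelSpec(in_channels=3, base_width=4), seed=5)
        m.input_scale, m.target_scale = 2.5, 0.7
        path = tmp_path / "model.npz"
        save_model(m, path)
        back = load_model(path)
        x = rng.random((1, 3, 32, 32)).astype(np.float32)
        np.testing.assert_allclose(m.forward(x), back.forward(x), atol=1e-7)
        assert back.input_scale == 2.5 and back.target_scale == 0.7

    def test_neighbor_channels_carry_signal(self, small_phantom, rng):
        # zeroing the neighbor channels of a (briefly) trained 3N model
        # degrades agreement with its own intact prediction
        from octasv.ablation import build_dataset

        _, vol, _ = small_phantom
        X, Y, isc, tsc = build_dataset([vol], C=3)
        m = build_model(ModelSpec(in_channels=3), seed=0)
        m.input_scale, m.target_scale = isc, tsc
        train(m, X, Y, TrainConfig(loss="mse", epochs=5, seed=0, lr=2e-3))
        intact = m.forward(X[:8].astype(np.float32))
        ablated_in = X[:8].copy()
        ablated_in[:, 0] = 0
        ablated_in[:, 2] = 0
        ablated = m.forward(ablated_in.astype(np.float32))
        target = Y[:8]
        err_intact = float(np.mean((intact - target) ** 2))
        err_ablated = float(np.mean((ablated - target) ** 2))
        assert err_ablated > err_intact
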