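"""U-Net construction, shape contracts, classification and gradients."""

import numpy as np
import pytest

from octskin.nn.layers import BatchNorm, ConvND, ConvTranspose, MaxPool
from octskin.nn.unet import (
    Adam,
    UNetConfig,
    build_unet,
    classify,
    cross_entropy,
    load_checkpoint,
    save_checkpoint,
    softmax,
)


def small_config(dims=2, **kw):
    kw.setdefault("n_stages", 3)
    kw.setdefault("base_features", 4)
    return UNetConfig(dims=dims, **kw)


class TestConfig:
    def test_default_encoder_widths(self):
        cfg = UNetConfig()
        assert [cfg.features(s) for s in range(1, 6)] == [32, 64, 128, 256, 512]

    def test_width_multiplier_scales(self):
        cfg = UNetConfig(width_multiplier=0.25)
        assert [cfg.features(s) for s in range(1, 6)] == [8, 16, 32, 64, 128]

    def test_width_floor_is_one(self):
        cfg = UNetConfig(base_features=2, width_multiplier=0.1)
        assert cfg.features(1) == 1

    @pytest.mark.parametrize("bad", [dict(dims=4), dict(width_multiplier=0.0)])
    def test_invalid_config(self, bad):
        with pytest.raises(ValueError):
            UNetConfig(**bad)


class TestShapes:
    def test_2d_output_matches_input(self):
        net = build_unet(small_config(2, seed=1))
        y = net.forward(np.zeros((1, 1, 32, 64), dtype=np.float32))
        assert y.shape == (1, 5, 32, 64)

    def test_3d_output_matches_input(self):
        net = build_unet(small_config(3, seed=1))
        y = net.forward(np.zeros((1, 1, 16, 8, 8), dtype=np.float32))
        assert y.shape == (1, 5, 16, 8, 8)

    def test_indivisible_spatial_dims_rejected(self):
        net = build_unet(small_config(2))  # 3 stages -> divisor 4
        with pytest.raises(ValueError, match="divisible"):
            net.forward(np.zeros((1, 1, 30, 64), dtype=np.float32))

    def test_parameter_count_quadruples_with_width(self):
        lo = build_unet(UNetConfig(n_stages=3, base_features=16, width_multiplier=0.5))
        hi = build_unet(UNetConfig(n_stages=3, base_features=16, width_multiplier=1.0))
        ratio = hi.n_parameters / lo.n_parameters
        assert 3.0 < ratio < 5.0


class TestForward:
    def test_eval_mode_deterministic(self, rng):
        net = build_unet(small_config(2, seed=3))
        x = rng.random((2, 1, 16, 16), dtype=np.float32)
        np.testing.assert_array_equal(
            net.forward(x, train=False), net.forward(x, train=False)
        )

    def test_same_seed_reproducible_networks(self, rng):
        x = rng.random((1, 1, 16, 16), dtype=np.float32)
        a = build_unet(small_config(2, seed=5)).forward(x)
        b = build_unet(small_config(2, seed=5)).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_zero_head_gives_zero_scores(self, rng):
        net = build_unet(small_config(2, seed=1))
        net.head.W[...] = 0.0
        net.head.b[...] = 0.0
        y = net.forward(rng.random((1, 1, 16, 16), dtype=np.float32))
        np.testing.assert_array_equal(y, 0.0)


class TestClassify:
    def test_one_hot_confidences(self):
        scores = np.zeros((5, 4, 4))
        scores[2, :, :] = 1.0
        np.testing.assert_array_equal(classify(scores), 3)

    def test_tie_breaks_to_lowest_class(self):
        scores = np.ones((5, 3, 3))
        np.testing.assert_array_equal(classify(scores), 1)

    def test_matches_brute_force_argmax(self, rng):
        scores = rng.random((5, 6, 7))
        got = classify(scores)
        for i in range(6):
            for j in range(7):
                best, best_v = 1, scores[0, i, j]
                for c in range(5):
                    if scores[c, i, j] > best_v:
                        best, best_v = c + 1, scores[c, i, j]
                assert got[i, j] == best

    def test_invariant_to_constant_channel_shift(self, rng):
        scores = rng.random((5, 8, 8))
        np.testing.assert_array_equal(classify(scores), classify(scores + 17.0))


class TestGradients:
    """Analytic gradients of every layer type against central differences."""

    @pytest.mark.parametrize(
        "layer,xshape",
        [
            (lambda rng: ConvND(2, 3, 2, rng), (2, 2, 6, 6)),
            (lambda rng: ConvND(1, 2, 3, rng), (1, 1, 4, 4, 4)),
            (lambda rng: ConvTranspose(2, 3, 2, rng), (2, 2, 4, 4)),
            (lambda rng: BatchNorm(2), (2, 2, 5, 5)),
        ],
    )
    def test_param_and_data_gradients(self, layer, xshape):
        rng = np.random.default_rng(0)
        lay = layer(rng)
        x = rng.random(xshape).astype(np.float32)
        y = lay.forward(x, train=True)
        dy = rng.random(y.shape).astype(np.float32)
        dx = lay.backward(dy)

        def loss(xv):
            return float((lay.forward(xv, train=True) * dy).sum())

        eps = 1e-3
        for _ in range(5):
            idx = tuple(rng.integers(s) for s in xshape)
            xp = x.copy()
            xp[idx] += eps
            xm = x.copy()
            xm[idx] -= eps
            num = (loss(xp) - loss(xm)) / (2 * eps)
            assert num == pytest.approx(float(dx[idx]), abs=2e-2)

    def test_maxpool_routes_gradient_to_argmax(self):
        pool = MaxPool(2)
        x = np.arange(16, dtype=np.float32).reshape(1, 1, 4, 4)
        y = pool.forward(x)
        np.testing.assert_array_equal(y[0, 0], [[5, 7], [13, 15]])
        dx = pool.backward(np.ones_like(y))
        expected = np.zeros_like(x)
        expected[0, 0][[1, 1, 3, 3], [1, 3, 1, 3]] = 1.0
        np.testing.assert_array_equal(dx, expected)

    def test_unet_end_to_end_gradient(self, rng):
        net = build_unet(small_config(2, seed=2))
        x = rng.random((1, 1, 8, 8), dtype=np.float32)
        t = rng.integers(1, 6, size=(1, 8, 8))
        net.zero_grad()
        scores = net.forward(x, train=True)
        _, ds = cross_entropy(scores, t)
        net.backward(ds)
        params, grads = net.parameters()
        prng = np.random.default_rng(1)
        for _ in range(6):
            pi = int(prng.integers(len(params)))
            idx = tuple(prng.integers(s) for s in params[pi].shape)
            eps = 1e-3
            old = params[pi][idx]
            params[pi][idx] = old + eps
            lp, _ = cross_entropy(net.forward(x, train=True), t)
            params[pi][idx] = old - eps
            lm, _ = cross_entropy(net.forward(x, train=True), t)
            params[pi][idx] = old
            assert (lp - lm) / (2 * eps) == pytest.approx(
                float(grads[pi][idx]), abs=5e-3
            )


class TestTrainingMachinery:
    def test_softmax_normalizes(self, rng):
        p = softmax(rng.random((2, 5, 3, 3)), axis=1)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-6)

    def test_cross_entropy_perfect_prediction_near_zero(self):
        scores = np.zeros((1, 5, 2, 2), dtype=np.float32)
        scores[0, 2] = 50.0
        t = np.full((1, 2, 2), 3)
        loss, _ = cross_entropy(scores, t)
        assert loss == pytest.approx(0.0, abs=1e-6)

    def test_adam_reduces_quadratic(self):
        p = np.array([5.0], dtype=np.float32)
        g = np.zeros_like(p)
        opt = Adam([p], [g], lr=0.1, betas=(0.9, 0.98))
        for _ in range(200):
            g[...] = 2 * p
            opt.step()
        assert abs(p[0]) < 0.5

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = build_unet(small_config(2, seed=4))
        x = rng.random((1, 1, 16, 16), dtype=np.float32)
        save_checkpoint(net, tmp_path / "w.npz")
        back = load_checkpoint(tmp_path / "w.npz")
        assert back.config == net.config
        np.testing.assert_array_equal(back.forward(x), net.forward(x))
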