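import numpy as np
import pytest

from wildcount.annotation import PatchPair
from wildcount.model import (
    ModelConfig,
    TrainConfig,
    build_unet,
    tversky_loss,
    _tversky_grad,
    train_base_model,
    predict_patch,
    save_model,
    load_model,
)

TINY_MODEL = ModelConfig(depth=2, base_filters=4, input_size=16)


def _tiny_pairs(n, seed, size=16, learnable=True):
    """Patches with a dark 3x3 blob on a bright background (or pure noise)."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n):
        img = rng.normal(0.6, 0.05, size=(4, size, size)).astype(np.float32)
        mask = np.zeros((size, size), dtype=np.uint8)
        if learnable:
            r, c = rng.integers(2, size - 2, size=2)
            img[:, r - 1 : r + 2, c - 1 : c + 2] *= 0.3
            mask[r - 1 : r + 2, c - 1 : c + 2] = 1
        pairs.append(PatchPair(img, mask, patch_id=f"t{i}"))
    return pairs


class TestTverskyLoss:
    def test_zero_on_perfect_binary_agreement(self):
        rng = np.random.default_rng(0)
        t = (rng.random((32, 32)) > 0.9).astype(float)
        assert tversky_loss(t, t, smooth=1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_limit_one_when_no_true_positives(self):
        t = np.zeros((16, 16))
        t[4, 4] = 1
        p = np.zeros_like(t)
        assert tversky_loss(p, t, smooth=1e-9) == pytest.approx(1.0, abs=1e-6)

    def test_equals_dice_at_symmetric_weights(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            p = rng.random((10, 10))
            t = (rng.random((10, 10)) > 0.7).astype(float)
            s = 1e-12
            ours = tversky_loss(p, t, 0.5, 0.5, s)
            dice = 1.0 - (2 * (p * t).sum() + 2 * s) / (p.sum() + t.sum() + 2 * s)
            assert ours == pytest.approx(dice, abs=1e-9)

    def test_spatial_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(64)
        t = (rng.random(64) > 0.8).astype(float)
        perm = rng.permutation(64)
        assert tversky_loss(p, t) == pytest.approx(tversky_loss(p[perm], t[perm]))

    def test_monotone_in_true_positive_mass(self):
        # closed form: fixing FP and FN, more TP mass lowers the loss
        def closed(tp, fp, fn, a=0.1, b=0.9, s=1.0):
            return 1 - (tp + s) / (tp + a * fp + b * fn + s)

        rng = np.random.default_rng(3)
        for _ in range(50):
            fp, fn = rng.uniform(0, 50, 2)
            tp = np.sort(rng.uniform(0, 50, 2))
            assert closed(tp[1], fp, fn) <= closed(tp[0], fp, fn) + 1e-12

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            tversky_loss(np.zeros((3, 3)), np.zeros((4, 4)))

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.1, 0.9, size=(6, 6))
        t = (rng.random((6, 6)) > 0.6).astype(float)
        g = _tversky_grad(p, t, 0.1, 0.9, 1.0)
        eps = 1e-6
        for idx in [(0, 0), (2, 3), (5, 5)]:
            p2 = p.copy()
            p2[idx] += eps
            num = (tversky_loss(p2, t) - tversky_loss(p, t)) / eps
            assert g[idx] == pytest.approx(num, rel=1e-3, abs=1e-8)


class TestUNet:
    def test_output_shape_and_sigmoid_range(self):
        model = build_unet(TINY_MODEL, seed=0)
        x = np.random.default_rng(0).random((2, 16, 16, 4)).astype(np.float32)
        p = model.forward(x)
        assert p.shape == (2, 16, 16, 1)
        assert p.min() >= 0 and p.max() <= 1

    def test_seeded_builds_are_identical(self):
        w1 = build_unet(TINY_MODEL, seed=5).get_weights()
        w2 = build_unet(TINY_MODEL, seed=5).get_weights()
        for a, b in zip(w1, w2):
            np.testing.assert_array_equal(a, b)

    def test_input_size_divisibility_contract(self):
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(depth=4, base_filters=4, input_size=100)

    def test_conv_backward_matches_float64_reference(self):
        from wildcount.nn import Conv

        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 8, 8, 3)).astype(np.float32)
        layer = Conv(rng, 3, 4, relu=True)
        y = layer.forward(x.copy(), train=True)
        w = rng.standard_normal(y.shape).astype(np.float32)
        dx = layer.backward(w.copy())

        W = layer.W.astype(np.float64)
        xp = np.pad(x.astype(np.float64), ((0, 0), (1, 1), (1, 1), (0, 0)))
        N, H, Wd, _ = x.shape
        pre = np.zeros((N, H, Wd, 4)) + layer.b
        for ky in range(3):
            for kx in range(3):
                pre += xp[:, ky : ky + H, kx : kx + Wd, :] @ W[ky, kx]
        dy = w.astype(np.float64) * (pre > 0)
        dxp = np.zeros_like(xp)
        dW = np.zeros_like(W)
        for ky in range(3):
            for kx in range(3):
                dxp[:, ky : ky + H, kx : kx + Wd, :] += dy @ W[ky, kx].T
                dW[ky, kx] = np.einsum(
                    "nhwc,nhwo->co", xp[:, ky : ky + H, kx : kx + Wd, :], dy
                )
        np.testing.assert_allclose(dx, dxp[:, 1:-1, 1:-1, :], rtol=1e-4, atol=1e-5)
        np.testing.assert_allclose(layer.dW, dW, rtol=1e-4, atol=1e-4)


class TestTraining:
    def test_learnable_blobs_reduce_validation_loss(self):
        train = _tiny_pairs(12, 0)
        val = _tiny_pairs(4, 99)
        tcfg = TrainConfig(learning_rate=3e-3, epochs=8, batch_size=4,
                           augment_data=False, seed=0)
        model, hist = train_base_model(train, val, TINY_MODEL, tcfg)
        assert hist["val_loss"].min() < hist["val_loss"].iloc[0]

    def test_checkpoint_is_minimum_validation_loss(self):
        train = _tiny_pairs(8, 1)
        val = _tiny_pairs(4, 98)
        tcfg = TrainConfig(learning_rate=3e-3, epochs=6, batch_size=4,
                           augment_data=False, seed=1)
        model, hist = train_base_model(train, val, TINY_MODEL, tcfg)
        from wildcount.model import _stack_pairs, _dataset_loss

        x_val, y_val = _stack_pairs(val)
        final = _dataset_loss(model, x_val, y_val, tcfg)
        assert final == pytest.approx(hist["val_loss"].min(), abs=1e-6)

    def test_plateau_reduces_learning_rate(self):
        # a learning rate of ~0 freezes the model, forcing a plateau
        train = _tiny_pairs(4, 2)
        val = _tiny_pairs(2, 97)
        tcfg = TrainConfig(learning_rate=1e-20, epochs=6, batch_size=4,
                           plateau_patience=2, plateau_factor=0.33,
                           augment_data=False, seed=2)
        _, hist = train_base_model(train, val, TINY_MODEL, tcfg)
        lrs = hist["learning_rate"].to_numpy()
        assert lrs[0] == pytest.approx(1e-20)
        assert lrs[-1] < lrs[0]  # at least one 0.33 cut happened
        assert np.isclose(lrs[lrs < lrs[0]][0], 1e-20 * 0.33)

    def test_identical_seeds_identical_history(self):
        tcfg = TrainConfig(learning_rate=1e-3, epochs=2, batch_size=4,
                           augment_data=False, seed=3)
        _, h1 = train_base_model(_tiny_pairs(6, 5), _tiny_pairs(2, 96),
                                 TINY_MODEL, tcfg)
        _, h2 = train_base_model(_tiny_pairs(6, 5), _tiny_pairs(2, 96),
                                 TINY_MODEL, tcfg)
        np.testing.assert_array_equal(h1.to_numpy(), h2.to_numpy())

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            train_base_model([], _tiny_pairs(2, 0), TINY_MODEL, TrainConfig())


class TestPredict:
    def test_prediction_shape_range_and_determinism(self):
        model = build_unet(TINY_MODEL, seed=0)
        img = np.random.default_rng(1).random((4, 16, 16)).astype(np.float32)
        p1 = predict_patch(model, img)
        p2 = predict_patch(model, img)
        assert p1.shape == (16, 16)
        assert 0 <= p1.min() and p1.max() <= 1
        np.testing.assert_array_equal(p1, p2)

    def test_size_mismatch_rejected(self):
        model = build_unet(TINY_MODEL, seed=0)
        with pytest.raises(ValueError, match="does not match"):
            predict_patch(model, np.zeros((4, 32, 32), dtype=np.float32))

    def test_save_load_round_trip(self, tmp_path):
        model = build_unet(TINY_MODEL, seed=4)
        img = np.random.default_rng(2).random((4, 16, 16)).astype(np.float32)
        save_model(model, tmp_path / "m")
        loaded = load_model(tmp_path / "m")
        np.testing.assert_array_equal(predict_patch(model, img),
                                      predict_patch(loaded, img))
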