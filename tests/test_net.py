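import numpy as np
import pytest

import cereflow.net as net_mod
from cereflow.net import (
    NetworkConfig,
    TrainConfig,
    build_dense_unet,
    center_crop_or_pad,
    composite_loss,
    load_model,
    predict_mask,
    restore_dims,
    save_model,
    train_model,
)
from cereflow.net import _loss_and_dlogits, softmax


def _mini_cfg(dims=(16, 16, 16), dropout=0.1):
    return NetworkConfig(
        input_dims=dims, levels=2, convs_per_dense_block=1,
        growth_rate=4, stem_filters=4, dropout=dropout,
    )


def _toy_case(dims=(16, 16, 16), seed=0):
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(dims).astype(np.float32)
    t = np.zeros(dims, np.uint8)
    t[4:10, 4:10, 4:10] = 1
    x[t.astype(bool)] += 3.0
    return x, t


class TestCenterCropOrPad:
    def test_crop_offsets_follow_margin_arithmetic(self):
        vol = np.zeros((256, 256, 72))
        vol[16, 32, 4] = 1.0  # should land at the new origin
        out = center_crop_or_pad(vol, (224, 192, 64))
        assert out.shape == (224, 192, 64)
        assert out[0, 0, 0] == 1.0

    def test_identity_when_already_at_target(self):
        vol = np.random.default_rng(0).random((8, 9, 10))
        assert center_crop_or_pad(vol, (8, 9, 10)) is vol

    def test_padding_adds_zeros_and_preserves_sum(self):
        vol = np.random.default_rng(1).random((20, 18, 6))
        out = center_crop_or_pad(vol, (22, 24, 8))
        assert out.shape == (22, 24, 8)
        assert out.sum() == pytest.approx(vol.sum())

    def test_odd_difference_extra_voxel_on_high_side(self):
        vol = np.arange(7.0)[:, None, None] * np.ones((7, 1, 1))
        out = center_crop_or_pad(vol, (4, 1, 1))
        # crop removes 1 low, 2 high: keeps indices 1..4
        np.testing.assert_array_equal(out[:, 0, 0], [1, 2, 3, 4])
        padded = center_crop_or_pad(out, (7, 1, 1))
        # pad 3: 1 voxel low side, 2 high side
        np.testing.assert_array_equal(padded[:, 0, 0], [0, 1, 2, 3, 4, 0, 0])

    def test_restore_dims_inverts_padding(self):
        vol = np.random.default_rng(2).random((10, 12, 14))
        big = center_crop_or_pad(vol, (16, 16, 16))
        np.testing.assert_array_equal(restore_dims(big, (10, 12, 14)), vol)


class TestArchitecture:
    def test_descriptor_channel_bookkeeping(self):
        model = build_dense_unet(_mini_cfg(), seed=0)
        d = model.describe()
        by_stage = {s["stage"]: s for s in d["stages"]}
        # stem 1->4; encoder block 4 + 4 = 8; bottleneck 8 + 4 = 12;
        # upconv 12 -> 6; decoder (8 skip + 6) + 4 = 18; head -> 2
        assert by_stage["stem"]["out_channels"] == 4
        assert by_stage["encoder0"]["out_channels"] == 8
        assert by_stage["bottleneck"]["out_channels"] == 12
        assert by_stage["upconv0"]["out_channels"] == 6
        assert by_stage["decoder0"]["out_channels"] == 18
        assert by_stage["head"]["out_channels"] == 2
        assert d["n_maxpool"] == 1
        assert d["n_transposed_conv"] == 1

    def test_parameter_count_matches_hand_derivation(self):
        model = build_dense_unet(_mini_cfg(), seed=0)
        expected = (
            (27 * 1 * 4 + 4)        # stem conv
            + (2 * 4 + 27 * 4 * 4 + 4)    # encoder: BN(4) + conv 4->4
            + (2 * 8 + 27 * 8 * 4 + 4)    # bottleneck: BN(8) + conv 8->4
            + (12 * 6 * 8 + 6)            # transposed conv 12->6, 2^3 kernel
            + (2 * 14 + 27 * 14 * 4 + 4)  # decoder: BN(14) + conv 14->4
            + (18 * 2 + 2)                # 1x1x1 head
        )
        assert model.n_parameters == expected

    def test_output_dims_equal_input_dims(self):
        model = build_dense_unet(_mini_cfg((8, 16, 24)), seed=0)
        x = np.zeros((8, 16, 24), np.float32)
        assert model.forward(x).shape == (2, 8, 16, 24)

    def test_same_seed_builds_identical_parameters(self):
        a = build_dense_unet(_mini_cfg(), seed=5)
        b = build_dense_unet(_mini_cfg(), seed=5)
        for (oa, na), (ob, nb) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(getattr(oa, na), getattr(ob, nb))

    def test_indivisible_dims_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(input_dims=(15, 16, 16), levels=2)


class TestCompositeLoss:
    def test_perfect_prediction_near_zero(self):
        t = np.zeros((4, 4, 4), np.uint8)
        t[1:3] = 1
        probs = np.stack([1.0 - t, t]).astype(float)
        assert composite_loss(probs, t) <= 1e-4

    def test_uniform_probabilities_give_ln2_cross_entropy(self):
        t = (np.random.default_rng(0).random((5, 5, 5)) > 0.5).astype(np.uint8)
        probs = np.full((2, 5, 5, 5), 0.5)
        ce_only = composite_loss(probs, t, ce_w=1.0, dice_w=0.0)
        assert ce_only == pytest.approx(np.log(2), abs=1e-9)

    def test_dice_loss_closed_form(self):
        t = np.ones((6, 6, 6), np.uint8)
        probs = np.stack([np.full(t.shape, 0.2), np.full(t.shape, 0.8)])
        dice_only = composite_loss(probs, t, ce_w=0.0, dice_w=1.0)
        n = t.size
        eps = 1e-5
        expected = 1.0 - (1.6 * n + eps) / (1.8 * n + eps)
        assert dice_only == pytest.approx(expected, abs=1e-9)
        assert dice_only == pytest.approx(0.1111, abs=1e-3)

    def test_permutation_invariant_over_voxels(self):
        rng = np.random.default_rng(4)
        t = (rng.random(60) > 0.5).astype(np.uint8)
        p1 = rng.uniform(0.01, 0.99, 60)
        probs = np.stack([1 - p1, p1]).reshape(2, 3, 4, 5)
        base = composite_loss(probs, t.reshape(3, 4, 5))
        perm = rng.permutation(60)
        shuffled = composite_loss(
            np.stack([1 - p1[perm], p1[perm]]).reshape(2, 3, 4, 5),
            t[perm].reshape(3, 4, 5),
        )
        assert shuffled == pytest.approx(base, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            composite_loss(np.full((2, 3, 3, 3), 0.5), np.zeros((4, 4, 4)))


class TestGradients:
    def test_backprop_matches_finite_differences(self, monkeypatch):
        monkeypatch.setattr(net_mod, "_DT", np.float64)
        cfg = NetworkConfig(input_dims=(4, 4, 4), levels=2,
                            convs_per_dense_block=2, growth_rate=2,
                            stem_filters=2, dropout=0.0)
        model = build_dense_unet(cfg, seed=3)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 4, 4))
        t = (rng.random((4, 4, 4)) > 0.7).astype(np.uint8)

        def loss():
            return _loss_and_dlogits(model.forward(x, training=True), t, 1.0, 1.0)[0]

        _, dl = _loss_and_dlogits(model.forward(x, training=True), t, 1.0, 1.0)
        model.backward(dl)
        for o, n in model.parameters():
            W, g = getattr(o, n), getattr(o, "d" + n)
            idx = np.unravel_index(int(rng.integers(W.size)), W.shape)
            eps, orig = 1e-6, float(W[idx])
            W[idx] = orig + eps
            lp = loss()
            W[idx] = orig - eps
            lm = loss()
            W[idx] = orig
            num = (lp - lm) / (2 * eps)
            assert float(g[idx]) == pytest.approx(num, abs=1e-6, rel=1e-4)


class TestTraining:
    def test_loss_decreases_under_gradient_descent_on_toy_problem(self):
        cfg = NetworkConfig(input_dims=(4, 4, 4), levels=1,
                            convs_per_dense_block=1, growth_rate=2,
                            stem_filters=2, dropout=0.0)
        model = build_dense_unet(cfg, seed=1)
        x, t = np.meshgrid(*[np.arange(4)] * 3, indexing="ij")[0].astype(np.float32), None
        t = (x > 1).astype(np.uint8)
        h = train_model(model, TrainConfig(learning_rate=1e-2, epochs=6, seed=0),
                        [(x, t)])
        losses = h["train_loss"]
        assert all(b < a for a, b in zip(losses, losses[1:]))

    def test_zero_learning_rate_leaves_loss_unchanged(self):
        cfg = _mini_cfg(dims=(8, 8, 8), dropout=0.0)
        model = build_dense_unet(cfg, seed=2)
        x, t = _toy_case((8, 8, 8))
        h = train_model(model, TrainConfig(learning_rate=0.0, epochs=3, seed=0),
                        [(x, t)])
        assert max(h["train_loss"]) - min(h["train_loss"]) < 1e-6

    def test_history_length_equals_epochs(self):
        model = build_dense_unet(_mini_cfg(dims=(8, 8, 8)), seed=0)
        x, t = _toy_case((8, 8, 8))
        h = train_model(model, TrainConfig(learning_rate=1e-3, epochs=4, seed=0),
                        [(x, t)], [(x, t)])
        assert len(h["train_loss"]) == 4
        assert len(h["val_dice"]) == 4
        assert h["best_epoch"] is not None

    def test_dims_mismatch_rejected_before_first_step(self):
        model = build_dense_unet(_mini_cfg(dims=(8, 8, 8)), seed=0)
        x, t = _toy_case((16, 16, 16))
        with pytest.raises(ValueError, match="dims"):
            train_model(model, TrainConfig(epochs=1), [(x, t)])

    def test_training_reproducible_under_fixed_seed(self):
        x, t = _toy_case((8, 8, 8))
        runs = []
        for _ in range(2):
            model = build_dense_unet(_mini_cfg(dims=(8, 8, 8)), seed=4)
            h = train_model(model, TrainConfig(learning_rate=1e-3, epochs=3, seed=9),
                            [(x, t)])
            runs.append(h["train_loss"])
        assert abs(runs[0][-1] - runs[1][-1]) <= 1e-6


class TestPrediction:
    def test_exact_probability_ties_assigned_background(self):
        model = build_dense_unet(_mini_cfg(dims=(8, 8, 8)), seed=0)
        model.head.W[:] = 0.0
        model.head.b[:] = 0.0  # logits identical -> p = (0.5, 0.5)
        x, _ = _toy_case((8, 8, 8))
        mask = predict_mask(model, x)
        assert mask.labels.sum() == 0

    def test_inference_deterministic(self):
        model = build_dense_unet(_mini_cfg(dims=(8, 8, 8)), seed=0)
        x, _ = _toy_case((8, 8, 8))
        a = predict_mask(model, x)
        b = predict_mask(model, x)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_input_auto_cropped_and_restored(self):
        model = build_dense_unet(_mini_cfg(dims=(8, 8, 8)), seed=0)
        x, _ = _toy_case((11, 9, 13))
        mask = predict_mask(model, x)
        assert mask.labels.shape == (11, 9, 13)

    def test_softmax_rows_sum_to_one(self):
        logits = np.random.default_rng(0).standard_normal((2, 3, 3, 3))
        p = softmax(logits)
        np.testing.assert_allclose(p.sum(axis=0), 1.0, atol=1e-12)

    def test_save_load_round_trip_preserves_predictions(self, tmp_path):
        model = build_dense_unet(_mini_cfg(dims=(8, 8, 8)), seed=0)
        x, t = _toy_case((8, 8, 8))
        train_model(model, TrainConfig(learning_rate=1e-3, epochs=2, seed=0), [(x, t)])
        save_model(model, tmp_path / "m.npz")
        back = load_model(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            predict_mask(back, x).labels, predict_mask(model, x).labels
        )
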