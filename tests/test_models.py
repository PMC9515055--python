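"""Network variants, parameter accounting, loss, sampling, training."""

import numpy as np
import pytest

from bemseg import nn
from bemseg.models import (
    NetworkConfig,
    TrainConfig,
    VARIANTS,
    build_network,
    combined_loss,
    count_parameters,
    load_checkpoint,
    sample_patch,
    save_checkpoint,
    softmax_cross_entropy_and_grad,
    soft_dice_loss_and_grad,
    train,
)
from bemseg.volumes import CTVolume, LabelVolume

TINY = dict(n_classes_multi=5, channels=(3, 6))


def _conv_params(cin, cout, k=3):
    return (k**3 * cin + 1) * cout


def _block_params(cin, cout):
    return _conv_params(cin, cout) + 2 * cout + _conv_params(cout, cout) + 2 * cout


def _decoder_params(channels):
    return sum(
        _block_params(channels[i] + channels[i + 1], channels[i])
        for i in range(len(channels) - 1)
    )


class TestArchitecture:
    @pytest.mark.parametrize("variant", VARIANTS)
    def test_output_shapes_match_input_patch(self, variant):
        model = build_network(NetworkConfig(variant=variant, **TINY))
        x = nn.Tensor(np.zeros((1, 8, 8, 8), dtype=np.float32))
        multi, binary = model(x)
        assert multi.shape == (5, 8, 8, 8)
        if variant == "baseline":
            assert binary is None
        else:
            assert binary.shape == (2, 8, 8, 8)

    def test_indivisible_patch_raises(self):
        model = build_network(NetworkConfig(**TINY))
        with pytest.raises(ValueError, match="divisible"):
            model(nn.Tensor(np.zeros((1, 7, 8, 8), dtype=np.float32)))

    def test_lone_1x1x1_conv_parameter_count(self):
        conv = nn.Conv3d(32, 2, 1, np.random.default_rng(0))
        assert count_parameters(conv) == 66  # 32*2 weights + 2 biases

    def test_dual_a_adds_exactly_one_binary_head(self):
        base = count_parameters(build_network(NetworkConfig(variant="baseline", **TINY)))
        dual = count_parameters(build_network(NetworkConfig(variant="dual_a", **TINY)))
        c0 = TINY["channels"][0]
        assert dual - base == (c0 + 1) * 2

    def test_dual_d_adds_one_decoder_and_binary_head(self):
        base = count_parameters(build_network(NetworkConfig(variant="baseline", **TINY)))
        dual = count_parameters(build_network(NetworkConfig(variant="dual_d", **TINY)))
        ch = TINY["channels"]
        assert dual - base == _decoder_params(ch) + (ch[0] + 1) * 2

    def test_baseline_count_matches_closed_form(self):
        ch = TINY["channels"]
        C = TINY["n_classes_multi"]
        expected = (
            _block_params(1, ch[0])
            + sum(_block_params(ch[i], ch[i + 1]) for i in range(len(ch) - 1))
            + _decoder_params(ch)
            + (ch[0] + 1) * C
        )
        model = build_network(NetworkConfig(variant="baseline", **TINY))
        assert count_parameters(model) == expected

    def test_config_validation(self):
        with pytest.raises(ValueError, match="increasing"):
            NetworkConfig(channels=(8, 8))
        with pytest.raises(ValueError, match="n_classes"):
            NetworkConfig(n_classes_multi=1)
        with pytest.raises(ValueError, match="variant"):
            NetworkConfig(variant="dual_e")


class TestCombinedLoss:
    def test_two_voxel_hand_example(self):
        """Loss on explicitly given probabilities matches the written formulas."""
        # p has class axis first: p(class, voxel); targets [0, 1]
        p = np.array([[0.8, 0.3], [0.2, 0.7]])
        logits = np.log(p).reshape(2, 2, 1, 1)
        target = np.array([0, 1]).reshape(2, 1, 1)
        eps = 1e-5
        ce = -(np.log(0.8) + np.log(0.7)) / 2
        # class-0 prediction mass 0.8 + 0.3, target mass 1; overlap 0.8
        d0 = 1 - (2 * 0.8 + eps) / ((0.8 + 0.3) + 1 + eps)
        # class-1 prediction mass 0.2 + 0.7, target mass 1; overlap 0.7
        d1 = 1 - (2 * 0.7 + eps) / ((0.2 + 0.7) + 1 + eps)
        expected = ce + d0 + d1
        assert combined_loss(logits, None, target) == pytest.approx(expected, rel=1e-5)

    def test_loss_nonnegative_for_random_logits(self, rng):
        logits = rng.normal(size=(4, 6, 6, 6)).astype(np.float32) * 5
        blogits = rng.normal(size=(2, 6, 6, 6)).astype(np.float32) * 5
        target = rng.integers(0, 4, (6, 6, 6))
        assert combined_loss(logits, blogits, target) >= 0.0

    def test_loss_vanishes_at_perfect_prediction_with_large_margin(self):
        target = np.tile(np.arange(4).reshape(4, 1, 1), (1, 2, 2))  # all 4 classes
        logits = np.full((4, 4, 2, 2), -50.0, dtype=np.float32)
        for c in range(4):
            logits[c][target == c] = 50.0
        blogits = np.full((2, 4, 2, 2), -50.0, dtype=np.float32)
        blogits[1][target > 0] = 50.0
        blogits[0][target == 0] = 50.0
        assert combined_loss(logits, blogits, target) < 1e-3

    def test_baseline_loss_is_first_two_terms_exactly(self, rng):
        logits = rng.normal(size=(3, 4, 4, 4)).astype(np.float32)
        target = rng.integers(0, 3, (4, 4, 4))
        ce, _, p, g = softmax_cross_entropy_and_grad(logits, target)
        dice, _ = soft_dice_loss_and_grad(p, g)
        assert combined_loss(logits, None, target) == pytest.approx(ce + dice, rel=1e-6)

    def test_dual_loss_adds_binary_terms(self, rng):
        logits = rng.normal(size=(3, 4, 4, 4)).astype(np.float32)
        blogits = rng.normal(size=(2, 4, 4, 4)).astype(np.float32)
        target = rng.integers(0, 3, (4, 4, 4))
        plain = combined_loss(logits, None, target)
        full = combined_loss(logits, blogits, target)
        ce, _, p, g = softmax_cross_entropy_and_grad(blogits, (target > 0).astype(int))
        dice, _ = soft_dice_loss_and_grad(p, g)
        assert full == pytest.approx(plain + ce + dice, rel=1e-6)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            combined_loss(np.zeros((3, 4, 4, 4)), None, np.zeros((5, 5, 5), dtype=int))

    def test_nonfinite_logits_raise(self):
        bad = np.full((2, 2, 2, 2), np.nan)
        with pytest.raises(ValueError, match="finite"):
            combined_loss(bad, None, np.zeros((2, 2, 2), dtype=int))


class TestSamplePatch:
    def _pair(self, rng, shape=(6, 7, 8)):
        ct = CTVolume(rng.normal(size=shape).astype(np.float32))
        labels = LabelVolume(rng.integers(0, 3, shape), n_classes=3)
        return ct, labels

    def test_patch_equal_to_volume_returns_whole_volume(self, rng):
        ct, labels = self._pair(rng)
        hu, lab = sample_patch(ct, labels, (6, 7, 8), rng)
        np.testing.assert_array_equal(hu, ct.voxels)
        np.testing.assert_array_equal(lab, labels.labels)

    def test_patch_is_congruent_subgrid(self, rng):
        ct, labels = self._pair(rng)
        for _ in range(10):
            hu, lab = sample_patch(ct, labels, 4, rng)
            found = False
            for ox in range(3):
                for oy in range(4):
                    for oz in range(5):
                        sl = np.s_[ox : ox + 4, oy : oy + 4, oz : oz + 4]
                        if np.array_equal(hu, ct.voxels[sl]):
                            found = True
                            assert np.array_equal(lab, labels.labels[sl])
            assert found

    def test_origin_distribution_covers_all_valid_origins(self, rng):
        ct = CTVolume(np.arange(5 * 4 * 4, dtype=np.float32).reshape(5, 4, 4))
        labels = LabelVolume(np.zeros((5, 4, 4), dtype=int), n_classes=2)
        seen = set()
        for _ in range(200):
            hu, _ = sample_patch(ct, labels, (4, 4, 4), rng)
            seen.add(float(hu[0, 0, 0]))
        assert len(seen) == 2  # origins x=0 and x=1

    def test_volume_smaller_than_patch_raises(self, rng):
        ct, labels = self._pair(rng)
        with pytest.raises(ValueError, match="smaller"):
            sample_patch(ct, labels, 16, rng)


class TestTraining:
    def _one_patch_pair(self):
        rng = np.random.default_rng(0)
        lab = rng.integers(0, 4, (16, 16, 16))
        lab.ravel()[:4] = np.arange(4)  # every class present
        hu = lab * 400.0 - 200.0 + rng.normal(0, 30, lab.shape)
        return [(CTVolume(hu.astype(np.float32)), LabelVolume(lab, 4))]

    def test_overfit_single_patch_reaches_small_loss(self):
        """A tiny model pinned to one 16^3 patch drives the loss below 10%."""
        model = build_network(
            NetworkConfig(variant="baseline", n_classes_multi=4, channels=(4, 8))
        )
        cfg = TrainConfig(iterations=300, patch_size=16, seed=0, learning_rate=0.01)
        model, trace = train(model, self._one_patch_pair(), cfg)
        assert trace[-1] < 0.1 * trace[0]

    def test_zero_iterations_leaves_parameters_unchanged(self):
        model = build_network(NetworkConfig(**TINY))
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(iterations=0, patch_size=8, seed=0)
        model, trace = train(model, self._one_patch_pair(), cfg)
        assert len(trace) == 0
        for k, v in model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_same_seed_gives_identical_loss_traces(self):
        pairs = self._one_patch_pair()
        traces = []
        for _ in range(2):
            model = build_network(
                NetworkConfig(variant="dual_a", n_classes_multi=4, channels=(3, 6))
            )
            cfg = TrainConfig(iterations=10, patch_size=16, seed=5, learning_rate=0.01)
            _, trace = train(model, pairs, cfg)
            traces.append(trace)
        np.testing.assert_array_equal(traces[0], traces[1])

    def test_empty_training_split_raises(self):
        model = build_network(NetworkConfig(**TINY))
        with pytest.raises(ValueError, match="empty"):
            train(model, [], TrainConfig(iterations=1, patch_size=8, seed=0))


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, tmp_path, rng):
        model = build_network(NetworkConfig(variant="dual_b", **TINY), seed=3)
        patch = rng.normal(0, 300, (8, 8, 8)).astype(np.float32)
        before = model.predict_patch(patch)
        save_checkpoint(model, tmp_path / "ckpt.npz")
        restored = load_checkpoint(tmp_path / "ckpt.npz")
        after = restored.predict_patch(patch)
        np.testing.assert_array_equal(before[0], after[0])
        np.testing.assert_array_equal(before[1], after[1])
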