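"""Sliding-window assembly, standard argmax and BEM inference."""

import numpy as np
import pytest

from bemseg.inference import (
    PatchSpec,
    ProbabilityVolume,
    bem_combine,
    mask_to_binary,
    sliding_window_predict,
    standard_argmax,
)
from bemseg.volumes import BinaryMask, CTVolume, binarize_labels


def random_probability_volume(rng, n_classes=4, shape=(8, 8, 8)):
    raw = rng.random((n_classes,) + shape)
    return ProbabilityVolume(raw / raw.sum(axis=0, keepdims=True))


class _ConstantModel:
    """Stub emitting fixed probabilities regardless of input."""

    def __init__(self, probs, binary=None):
        self.probs = np.asarray(probs, dtype=np.float32)
        self.binary = binary

    def predict_patch(self, patch):
        shape = patch.shape
        multi = np.broadcast_to(
            self.probs[:, None, None, None], (len(self.probs),) + shape
        ).copy()
        if self.binary is None:
            return multi, None
        binary = np.broadcast_to(
            np.asarray(self.binary, np.float32)[:, None, None, None], (2,) + shape
        ).copy()
        return multi, binary


class _PositionModel:
    """Stub whose class-1 probability depends on the patch HU values."""

    def predict_patch(self, patch):
        p1 = 1.0 / (1.0 + np.exp(-patch / 500.0))
        return np.stack([1 - p1, p1]).astype(np.float32), None


class TestSlidingWindow:
    def test_constant_model_gives_constant_assembly(self, rng):
        ct = CTVolume(rng.normal(size=(10, 11, 12)).astype(np.float32))
        model = _ConstantModel([0.6, 0.3, 0.1])
        out, binary = sliding_window_predict(ct, model, PatchSpec(4, 1, 2))
        assert binary is None
        assert out.shape == ct.shape
        np.testing.assert_allclose(out.probs[0], 0.6, atol=1e-6)
        np.testing.assert_allclose(out.probs[2], 0.1, atol=1e-6)

    def test_single_tile_equals_direct_model_output(self, rng):
        ct = CTVolume(rng.normal(0, 400, size=(6, 6, 6)).astype(np.float32))
        model = _PositionModel()
        direct, _ = model.predict_patch(ct.voxels)
        out, _ = sliding_window_predict(ct, model, PatchSpec(6, 0, 0))
        np.testing.assert_allclose(out.probs, direct, atol=1e-6)

    def test_matches_accumulate_and_normalize_oracle(self, rng):
        """Tiled prediction equals a naive per-voxel accumulation."""
        ct = CTVolume(rng.normal(0, 400, size=(10, 9, 8)).astype(np.float32))
        model = _PositionModel()
        spec = PatchSpec(4, 2, 2)
        out, _ = sliding_window_predict(ct, model, spec)

        pad = spec.pad
        vol = np.pad(ct.voxels, pad, constant_values=-1024.0)
        acc = np.zeros((2,) + vol.shape)
        cnt = np.zeros(vol.shape)
        stride = spec.patch_size - spec.overlap

        def starts(n):
            s = list(range(0, n - spec.patch_size + 1, stride))
            if s[-1] != n - spec.patch_size:
                s.append(n - spec.patch_size)
            return s

        for sx in starts(vol.shape[0]):
            for sy in starts(vol.shape[1]):
                for sz in starts(vol.shape[2]):
                    sl = np.s_[sx:sx + 4, sy:sy + 4, sz:sz + 4]
                    p, _ = model.predict_patch(vol[sl])
                    acc[(slice(None),) + sl] += p
                    cnt[sl] += 1
        expected = (acc / cnt)[:, pad:-pad, pad:-pad, pad:-pad]
        np.testing.assert_allclose(out.probs, expected, atol=1e-6)

    def test_probabilities_sum_to_one(self, rng):
        ct = CTVolume(rng.normal(0, 400, size=(9, 9, 9)).astype(np.float32))
        out, _ = sliding_window_predict(ct, _PositionModel(), PatchSpec(4, 1, 1))
        sums = out.probs.sum(axis=0, dtype=np.float64)
        assert np.abs(sums - 1).max() < 1e-5

    def test_volume_smaller_than_patch_raises(self, rng):
        ct = CTVolume(np.zeros((3, 3, 3), dtype=np.float32))
        with pytest.raises(ValueError, match="smaller"):
            sliding_window_predict(ct, _PositionModel(), PatchSpec(16, 0, 0))


class TestStandardArgmax:
    def test_one_hot_recovers_labels(self, rng):
        labels = rng.integers(0, 4, (5, 5, 5))
        probs = np.zeros((4, 5, 5, 5), dtype=np.float32)
        for c in range(4):
            probs[c][labels == c] = 1.0
        out = standard_argmax(ProbabilityVolume(probs))
        np.testing.assert_array_equal(out.labels, labels)

    def test_uniform_tie_goes_to_background(self):
        probs = np.full((4, 2, 2, 2), 0.25, dtype=np.float32)
        out = standard_argmax(ProbabilityVolume(probs))
        assert np.all(out.labels == 0)

    def test_matches_per_voxel_loop_oracle(self, rng):
        P = random_probability_volume(rng, 5, (4, 4, 4))
        out = standard_argmax(P)
        for idx in np.ndindex(*P.shape):
            probs_here = [P.probs[(c,) + idx] for c in range(5)]
            assert out.labels[idx] == int(np.argmax(probs_here))


class TestBemCombine:
    def test_zero_mask_forces_background(self, rng):
        P = random_probability_volume(rng)
        B = BinaryMask(np.zeros(P.shape, dtype=np.uint8))
        out = bem_combine(P, B)
        assert np.all(out.labels == 0)

    def test_foreground_argmax_ignores_dominant_background(self):
        probs = np.zeros((3, 1, 1, 1), dtype=np.float32)
        probs[:, 0, 0, 0] = [0.5, 0.3, 0.2]
        P = ProbabilityVolume(probs)
        B = BinaryMask(np.ones((1, 1, 1), dtype=np.uint8))
        assert standard_argmax(P).labels[0, 0, 0] == 0
        assert bem_combine(P, B).labels[0, 0, 0] == 1

    def test_matches_per_voxel_loop_oracle(self, rng):
        P = random_probability_volume(rng, 6, (8, 8, 8))
        B = BinaryMask(rng.integers(0, 2, (8, 8, 8)))
        out = bem_combine(P, B)
        for idx in np.ndindex(*P.shape):
            if B.mask[idx] == 0:
                assert out.labels[idx] == 0
            else:
                fg = [P.probs[(c,) + idx] for c in range(1, 6)]
                assert out.labels[idx] == int(np.argmax(fg)) + 1

    def test_support_identity(self, rng):
        """Output is nonzero exactly where the guide mask is 1, for any P."""
        for _ in range(5):
            P = random_probability_volume(rng, 4, (6, 6, 6))
            B = BinaryMask(rng.integers(0, 2, (6, 6, 6)))
            out = bem_combine(P, B)
            np.testing.assert_array_equal((out.labels > 0), (B.mask == 1))

    def test_own_support_mask_reproduces_standard_argmax(self, rng):
        P = random_probability_volume(rng, 5, (7, 7, 7))
        std = standard_argmax(P)
        out = bem_combine(P, binarize_labels(std))
        np.testing.assert_array_equal(out.labels, std.labels)

    def test_agreement_where_standard_picks_foreground_inside_mask(self, rng):
        """BEM only revises voxels whose background/foreground call changes."""
        P = random_probability_volume(rng, 5, (6, 6, 6))
        B = BinaryMask(rng.integers(0, 2, (6, 6, 6)))
        std = standard_argmax(P)
        bem = bem_combine(P, B)
        both_fg = (std.labels > 0) & (B.mask == 1)
        np.testing.assert_array_equal(bem.labels[both_fg], std.labels[both_fg])

    def test_shape_mismatch_raises(self, rng):
        P = random_probability_volume(rng)
        B = BinaryMask(np.zeros((3, 3, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="mismatch"):
            bem_combine(P, B)


class TestMaskToBinary:
    def test_one_hot_bone_voxels(self):
        probs = np.zeros((2, 2, 2, 2), dtype=np.float32)
        probs[1, 0] = 1.0
        probs[0, 1] = 1.0
        mask = mask_to_binary(ProbabilityVolume(probs))
        assert np.all(mask.mask[0] == 1)
        assert np.all(mask.mask[1] == 0)

    def test_exact_tie_counts_as_bone(self):
        probs = np.full((2, 2, 2, 2), 0.5, dtype=np.float32)
        assert np.all(mask_to_binary(ProbabilityVolume(probs)).mask == 1)

    def test_equals_standard_argmax_of_two_class_volume(self, rng):
        P = random_probability_volume(rng, 2, (6, 6, 6))
        np.testing.assert_array_equal(
            mask_to_binary(P).mask, standard_argmax(P).labels.astype(np.uint8)
        )

    def test_wrong_class_count_raises(self, rng):
        with pytest.raises(ValueError):
            mask_to_binary(random_probability_volume(rng, 3))
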