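"""Whole-volume prediction: sliding-window assembly, argmax and BEM.

Standard inference takes the per-voxel argmax over all classes including
background.  BEM (binary-prediction-enhanced multi-class) inference instead
uses a binary bone-tissue mask as a guide: a voxel is background exactly
where the mask is 0, and elsewhere receives the most probable *foreground*
class, with the background probability ignored.  Unlike masking a finished
multi-class prediction, this recovers foreground voxels that the multi-class
softmax would have lost to the background class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .volumes import BinaryMask, CTVolume, LabelVolume

__all__ = [
    "ProbabilityVolume",
    "PatchSpec",
    "sliding_window_predict",
    "standard_argmax",
    "bem_combine",
    "mask_to_binary",
]

#: HU fill value used when padding CT volumes (air)
PAD_FILL_HU = -1024.0


@dataclass
class ProbabilityVolume:
    """Per-voxel class probabilities; axis 0 is the class axis, class 0 = background."""

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float32)
        if self.probs.ndim != 4:
            raise ValueError(f"probs must be (N, X, Y, Z), got shape {self.probs.shape}")
        if self.probs.min() < -1e-5 or self.probs.max() > 1 + 1e-5:
            raise ValueError("probabilities outside [0, 1]")
        sums = self.probs.sum(axis=0, dtype=np.float64)
        if np.abs(sums - 1.0).max() > 1e-4:
            raise ValueError("per-voxel probabilities do not sum to 1")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.probs.shape[1:]


@dataclass
class PatchSpec:
    """Sliding-window geometry: patch size, inter-patch overlap, outer pad."""

    patch_size: int = 64
    overlap: int = 20
    pad: int = 20

    def __post_init__(self):
        if not (0 <= self.overlap < self.patch_size):
            raise ValueError("need 0 <= overlap < patch_size")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")


def _tile_starts(extent: int, patch: int, stride: int):
    """Window starts covering [0, extent); the last window sits flush."""
    if extent < patch:
        raise ValueError(f"extent {extent} smaller than patch {patch}")
    starts = list(range(0, extent - patch + 1, stride))
    if starts[-1] != extent - patch:
        starts.append(extent - patch)
    return starts


def sliding_window_predict(
    ct: CTVolume, model, spec: PatchSpec | None = None
) -> Tuple[ProbabilityVolume, Optional[ProbabilityVolume]]:
    """Assemble whole-volume softmax probabilities patchwise.

    The CT is padded by ``spec.pad`` voxels of air on every side, tiled with
    stride ``patch_size - overlap`` (last window per axis shifted flush to
    the end), per-patch softmax probabilities are averaged with uniform
    weights wherever windows overlap, and the result is cropped back to the
    original grid.

    ``model`` needs a ``predict_patch(hu_patch) -> (probs, probs_or_None)``
    method; the second element feeds the dual-head binary output through the
    same assembly.  Returns ``(multi, binary_or_None)``.
    """
    spec = spec or PatchSpec()
    p = spec.pad
    vol = np.pad(ct.voxels, p, constant_values=PAD_FILL_HU)
    size = spec.patch_size
    stride = size - spec.overlap
    starts = [_tile_starts(e, size, stride) for e in vol.shape]

    acc_multi = acc_bin = None
    count = np.zeros(vol.shape, dtype=np.float32)
    for sx in starts[0]:
        for sy in starts[1]:
            for sz in starts[2]:
                sl = np.s_[sx : sx + size, sy : sy + size, sz : sz + size]
                multi, binary = model.predict_patch(vol[sl])
                if acc_multi is None:
                    acc_multi = np.zeros((multi.shape[0],) + vol.shape, dtype=np.float32)
                    if binary is not None:
                        acc_bin = np.zeros((2,) + vol.shape, dtype=np.float32)
                acc_multi[(slice(None),) + sl] += multi
                if binary is not None:
                    acc_bin[(slice(None),) + sl] += binary
                count[sl] += 1.0
    crop = (slice(None),) + tuple(slice(p, n - p) for n in vol.shape)
    out_multi = (acc_multi / count)[crop]
    result_multi = ProbabilityVolume(out_multi)
    if acc_bin is None:
        return result_multi, None
    return result_multi, ProbabilityVolume((acc_bin / count)[crop])


def standard_argmax(P: ProbabilityVolume) -> LabelVolume:
    """Per-voxel argmax over all classes; ties go to the lowest class index."""
    return LabelVolume(
        np.argmax(P.probs, axis=0).astype(np.uint16), n_classes=P.n_classes
    )


def bem_combine(P: ProbabilityVolume, B: BinaryMask) -> LabelVolume:
    """Binary-prediction-enhanced multi-class inference.

    Voxels where the guide mask ``B`` is 0 become background; everywhere
    else the most probable *foreground* class (argmax over classes 1..N-1,
    background ignored) is assigned.  The output is therefore nonzero
    exactly on the support of ``B``.
    """
    if P.shape != B.shape:
        raise ValueError(f"shape mismatch: probs {P.shape} vs mask {B.shape}")
    if P.n_classes < 2:
        raise ValueError("need at least one foreground class")
    fg = np.argmax(P.probs[1:], axis=0).astype(np.uint16) + 1
    out = np.where(B.mask == 1, fg, 0).astype(np.uint16)
    return LabelVolume(out, n_classes=P.n_classes, spacing=B.spacing, affine=B.affine)


def mask_to_binary(P_binary: ProbabilityVolume) -> BinaryMask:
    """Threshold a 2-class probability volume; ties (0.5/0.5) count as bone."""
    if P_binary.n_classes != 2:
        raise ValueError(f"expected 2 classes, got {P_binary.n_classes}")
    return BinaryMask((P_binary.probs[1] >= P_binary.probs[0]).astype(np.uint8))
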