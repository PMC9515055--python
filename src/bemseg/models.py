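"""The baseline 3D U-Net and its four dual-segmentation-head variants.

All networks share the same trunk recipe: an encoder/decoder with skip
connections, two 3x3x3 convolutions per resolution level (each followed by
affine instance normalization and a leaky ReLU), parameter-free 2x
max-pooling on the way down, trilinear upsampling on the way up, and 1x1x1
classification heads.  The dual variants add a second, binary
(background/bone-tissue) output:

``dual_a``
    shared trunk, two 1x1x1 heads;
``dual_b``
    shared trunk, each head preceded by its own full-resolution conv block;
``dual_c``
    binary head directly on the decoder output, multi-class head after one
    more full-resolution conv block;
``dual_d``
    shared encoder, two separate decoders.

The default channel widths ``(26, 52, 104, 176, 444)`` are pinned so that
with 126 output classes the baseline counts 1.46e7 trainable parameters and
``dual_d`` 1.98e7 (3 significant figures).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import nn
from .volumes import CTVolume, LabelVolume, read_volume

__all__ = [
    "DEFAULT_CHANNELS",
    "VARIANTS",
    "NetworkConfig",
    "TrainConfig",
    "BemNet",
    "build_network",
    "count_parameters",
    "combined_loss",
    "softmax_cross_entropy_and_grad",
    "soft_dice_loss_and_grad",
    "sample_patch",
    "train",
    "save_checkpoint",
    "load_checkpoint",
]

#: widths pinned to reproduce the published parameter counts at C=126
DEFAULT_CHANNELS: Tuple[int, ...] = (26, 52, 104, 176, 444)

VARIANTS = ("baseline", "dual_a", "dual_b", "dual_c", "dual_d")

#: HU values are divided by this before entering the network
INPUT_HU_SCALE = 1000.0

DICE_EPS = 1e-5


@dataclass
class NetworkConfig:
    variant: str = "baseline"
    n_classes_multi: int = 126
    channels: Tuple[int, ...] = DEFAULT_CHANNELS
    leaky_slope: float = 0.01
    norm_epsilon: float = 1e-5

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.n_classes_multi < 2:
            raise ValueError("n_classes_multi must be >= 2")
        self.channels = tuple(int(c) for c in self.channels)
        if len(self.channels) < 2 or any(
            a >= b for a, b in zip(self.channels, self.channels[1:])
        ):
            raise ValueError("channels must be strictly increasing over encoder levels")

    @property
    def levels(self) -> int:
        return len(self.channels)

    def to_dict(self) -> dict:
        return dict(
            variant=self.variant,
            n_classes_multi=self.n_classes_multi,
            channels=list(self.channels),
            leaky_slope=self.leaky_slope,
            norm_epsilon=self.norm_epsilon,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**{**d, "channels": tuple(d["channels"])})


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    iterations: int = 75_000
    batch_size: int = 1
    patch_size: int = 64
    seed: int = 0

    def __post_init__(self):
        if self.batch_size != 1:
            raise ValueError("batch_size is fixed at 1")
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")


class _Encoder(nn.Module):
    def __init__(self, channels, rng, slope, eps):
        super().__init__()
        blocks = []
        c_in = 1
        for c in channels:
            blocks.append(nn.ConvBlock(c_in, c, rng, slope, eps))
            c_in = c
        self.blocks = blocks

    def __call__(self, x: nn.Tensor):
        skips = []
        for i, blk in enumerate(self.blocks):
            x = blk(x)
            if i < len(self.blocks) - 1:
                skips.append(x)
                x = nn.max_pool3d(x)
        return x, skips


class _Decoder(nn.Module):
    def __init__(self, channels, rng, slope, eps):
        super().__init__()
        blocks = []
        for i in range(len(channels) - 2, -1, -1):
            blocks.append(nn.ConvBlock(channels[i] + channels[i + 1], channels[i], rng, slope, eps))
        self.blocks = blocks

    def __call__(self, x: nn.Tensor, skips):
        for blk, skip in zip(self.blocks, reversed(skips)):
            x = nn.upsample3d(x, 2)
            x = blk(nn.concat(skip, x))
        return x


class BemNet(nn.Module):
    """U-Net mapping a 1-channel HU patch to multi-class (and binary) logits."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(np.random.SeedSequence([seed, 0xB0E]))
        ch = config.channels
        C = config.n_classes_multi
        slope, eps = config.leaky_slope, config.norm_epsilon
        self.encoder = _Encoder(ch, rng, slope, eps)
        self.decoder = _Decoder(ch, rng, slope, eps)
        self.head_multi = nn.Conv3d(ch[0], C, 1, rng)
        v = config.variant
        if v == "dual_a":
            self.head_bin = nn.Conv3d(ch[0], 2, 1, rng)
        elif v == "dual_b":
            self.block_multi = nn.ConvBlock(ch[0], ch[0], rng, slope, eps)
            self.block_bin = nn.ConvBlock(ch[0], ch[0], rng, slope, eps)
            self.head_bin = nn.Conv3d(ch[0], 2, 1, rng)
        elif v == "dual_c":
            self.block_multi = nn.ConvBlock(ch[0], ch[0], rng, slope, eps)
            self.head_bin = nn.Conv3d(ch[0], 2, 1, rng)
        elif v == "dual_d":
            self.decoder_bin = _Decoder(ch, rng, slope, eps)
            self.head_bin = nn.Conv3d(ch[0], 2, 1, rng)

    @property
    def is_dual(self) -> bool:
        return self.config.variant != "baseline"

    def _check_patch(self, shape):
        div = 2 ** (self.config.levels - 1)
        if any(s % div for s in shape):
            raise ValueError(
                f"patch shape {shape} must be divisible by {div} "
                f"({self.config.levels} resolution levels)"
            )

    def __call__(self, patch: nn.Tensor):
        """Returns ``(multi_logits, binary_logits or None)``, spatial shape preserved."""
        self._check_patch(patch.shape[-3:])
        if patch.data.ndim == 3:
            patch = nn.Tensor(patch.data[None], requires_grad=patch.requires_grad)
        bottom, skips = self.encoder(patch)
        v = self.config.variant
        if v == "dual_d":
            trunk = self.decoder(bottom, skips)
            trunk_bin = self.decoder_bin(bottom, skips)
            return self.head_multi(trunk), self.head_bin(trunk_bin)
        trunk = self.decoder(bottom, skips)
        if v == "baseline":
            return self.head_multi(trunk), None
        if v == "dual_a":
            return self.head_multi(trunk), self.head_bin(trunk)
        if v == "dual_b":
            return (
                self.head_multi(self.block_multi(trunk)),
                self.head_bin(self.block_bin(trunk)),
            )
        # dual_c: binary head on the decoder output, multi-class head after
        # one more full-resolution block
        return self.head_multi(self.block_multi(trunk)), self.head_bin(trunk)

    def predict_patch(self, hu_patch: np.ndarray):
        """Softmax probabilities for one HU patch (no gradient tape).

        Returns ``(multi_probs, binary_probs or None)`` with a leading class
        axis.
        """
        x = nn.Tensor(np.asarray(hu_patch, dtype=np.float32)[None] / INPUT_HU_SCALE)
        with nn.no_grad():
            multi, binary = self(x)
        return _softmax(multi.data), None if binary is None else _softmax(binary.data)


def build_network(config: NetworkConfig, seed: int = 0) -> BemNet:
    """Instantiate a network variant with reproducible weight initialization."""
    return BemNet(config, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Number of trainable scalar parameters."""
    return int(sum(p.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=0, keepdims=True)
    e = np.exp(z, dtype=np.float64)
    return (e / e.sum(axis=0, keepdims=True)).astype(np.float32)


def _one_hot(target: np.ndarray, n: int) -> np.ndarray:
    g = np.zeros((n,) + target.shape, dtype=np.float32)
    idx = np.indices(target.shape)
    g[(target,) + tuple(idx)] = 1.0
    return g


def softmax_cross_entropy_and_grad(logits: np.ndarray, target: np.ndarray):
    """Mean voxelwise cross-entropy of softmax(logits) and its logit gradient."""
    p = _softmax(logits)
    n_vox = target.size
    idx = tuple(np.indices(target.shape))
    logp = np.log(np.maximum(p[(target,) + idx], 1e-30))
    loss = -float(logp.mean())
    g = _one_hot(target, logits.shape[0])
    grad = (p - g) / n_vox
    return loss, grad.astype(np.float32), p, g


def soft_dice_loss_and_grad(p: np.ndarray, g: np.ndarray, eps: float = DICE_EPS):
    """Sum over classes of (1 - soft Dice) on probabilities, with d/dp.

    Per class c the soft Dice loss is ``1 - (2*sum(p_c*g_c)+eps) /
    (sum(p_c)+sum(g_c)+eps)``; classes absent from both target and
    prediction contribute 0 through the eps terms.
    """
    ax = tuple(range(1, p.ndim))
    spg = (p * g).sum(axis=ax, dtype=np.float64)
    sp = p.sum(axis=ax, dtype=np.float64)
    sg = g.sum(axis=ax, dtype=np.float64)
    num = 2.0 * spg + eps
    den = sp + sg + eps
    loss = float((1.0 - num / den).sum())
    sh = (-1,) + (1,) * (p.ndim - 1)
    dp = -(2.0 * g * den.reshape(sh) - num.reshape(sh)) / (den**2).reshape(sh)
    return loss, dp.astype(np.float32)


def _head_loss_and_grad(logits: np.ndarray, target: np.ndarray):
    """Cross-entropy + summed soft Dice for one head; gradient w.r.t. logits."""
    ce, dce, p, g = softmax_cross_entropy_and_grad(logits, target)
    dice, dp = soft_dice_loss_and_grad(p, g)
    # chain the Dice d/dp through the softmax
    inner = (dp * p).sum(axis=0, keepdims=True)
    ddice = p * (dp - inner)
    return ce + dice, (dce + ddice).astype(np.float32)


def combined_loss(
    multi_logits: np.ndarray,
    binary_logits: Optional[np.ndarray],
    gt_labels: np.ndarray,
) -> float:
    """The unweighted training loss.

    Multi-class cross-entropy plus per-class soft Dice losses, and — when a
    binary head is present — the same two terms for the binary
    background/bone-tissue task, whose target is derived on the fly as
    ``gt_labels > 0``.
    """
    loss, _, _ = _combined_loss_and_grads(multi_logits, binary_logits, gt_labels)
    return loss


def _combined_loss_and_grads(multi_logits, binary_logits, gt_labels):
    multi_logits = np.asarray(multi_logits, dtype=np.float32)
    target = np.asarray(gt_labels)
    if np.issubdtype(target.dtype, np.floating):
        target = np.round(target).astype(np.int64)
    else:
        target = target.astype(np.int64)
    if multi_logits.shape[1:] != target.shape:
        raise ValueError("multi_logits and gt_labels shapes disagree")
    if not np.all(np.isfinite(multi_logits)):
        raise ValueError("non-finite logits")
    loss, gmulti = _head_loss_and_grad(multi_logits, target)
    gbin = None
    if binary_logits is not None:
        binary_logits = np.asarray(binary_logits, dtype=np.float32)
        if binary_logits.shape[0] != 2 or binary_logits.shape[1:] != target.shape:
            raise ValueError("binary_logits must have 2 channels and matching shape")
        if not np.all(np.isfinite(binary_logits)):
            raise ValueError("non-finite logits")
        lb, gbin = _head_loss_and_grad(binary_logits, (target > 0).astype(np.int64))
        loss += lb
    return loss, gmulti, gbin


# ---------------------------------------------------------------------------
# patch sampling and training
# ---------------------------------------------------------------------------

def sample_patch(
    ct: CTVolume,
    labels: LabelVolume,
    size: int | Tuple[int, int, int],
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Random congruent crop of CT and labels (the only data augmentation)."""
    if isinstance(size, int):
        size = (size, size, size)
    shape = ct.shape
    if ct.shape != labels.shape:
        raise ValueError("CT and label shapes disagree")
    if any(s < p for s, p in zip(shape, size)):
        raise ValueError(f"volume {shape} smaller than patch {size}")
    origin = tuple(int(rng.integers(0, s - p + 1)) for s, p in zip(shape, size))
    sl = tuple(slice(o, o + p) for o, p in zip(origin, size))
    return ct.voxels[sl].copy(), labels.labels[sl].copy()


def _load_training_pairs(manifest) -> List[Tuple[CTVolume, LabelVolume]]:
    if isinstance(manifest, pd.DataFrame):
        rows = manifest[manifest["split"] == "train"]
        pairs = []
        for _, row in rows.iterrows():
            ct = read_volume(row["ct_path"], "ct")
            labels = read_volume(row["seg_path"], "labels")
            pairs.append((ct, labels))
        return pairs
    return list(manifest)


def train(model: BemNet, manifest, train_cfg: TrainConfig):
    """Patchwise Adam training; returns ``(model, loss_trace)``.

    ``manifest`` is either a dataset manifest DataFrame (rows with split ==
    'train' are used) or an in-memory list of (CTVolume, LabelVolume) pairs.
    One uniformly sampled patch per iteration (batch size 1); the loss of
    every step is recorded.  Deterministic for a fixed seed.
    """
    pairs = _load_training_pairs(manifest)
    if not pairs:
        raise ValueError("empty training split")
    size = train_cfg.patch_size
    for ct, labels in pairs:
        if any(s < size for s in ct.shape):
            raise ValueError(f"training volume {ct.shape} smaller than patch {size}")
    rng = np.random.default_rng(np.random.SeedSequence([train_cfg.seed, 0x7A41]))
    opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate)
    trace = np.zeros(train_cfg.iterations, dtype=np.float64)
    for it in range(train_cfg.iterations):
        ct, labels = pairs[int(rng.integers(len(pairs)))]
        hu, lab = sample_patch(ct, labels, size, rng)
        x = nn.Tensor(hu[None] / INPUT_HU_SCALE)
        multi, binary = model(x)
        loss, gmulti, gbin = _combined_loss_and_grads(
            multi.data, None if binary is None else binary.data, lab
        )
        trace[it] = loss
        opt.zero_grad()
        if binary is None:
            multi.backward(gmulti)
        else:
            nn.autograd.backward([multi, binary], [gmulti, gbin])
        opt.step()
    return model, trace


# ---------------------------------------------------------------------------
# checkpoints: npz weights + JSON sidecar with the network config
# ---------------------------------------------------------------------------

def save_checkpoint(model: BemNet, path) -> None:
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))


def load_checkpoint(path) -> BemNet:
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    config = NetworkConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
    model = BemNet(config)
    with np.load(path) as zf:
        model.load_state_dict({k: zf[k] for k in zf.files})
    return model
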