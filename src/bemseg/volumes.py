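"""Volume containers, NIfTI I/O, resampling and label/mask conversions.

All grids are indexed ``(x, y, z)`` in NIfTI storage order; shapes are
reported in that order throughout the package.  Three voxel-grid kinds are
distinguished:

``CTVolume``
    Hounsfield-unit scalar field (float).
``LabelVolume``
    Non-negative integer field; 0 is background, 1..N-1 are distinct bones.
``BinaryMask``
    {0, 1} field marking bone tissue vs everything else (the binary
    background/bone-tissue segmentation used to guide BEM inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "LabelVolume",
    "BinaryMask",
    "read_volume",
    "write_volume",
    "resample",
    "binarize_labels",
]

#: stored float labels may deviate from integers by at most this much
LABEL_ROUND_TOL = 1e-3

Spacing = Tuple[float, float, float]


def _default_affine(spacing: Spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _check_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be 3 positive reals, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """3D scalar field of Hounsfield units with voxel-spacing metadata."""

    voxels: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        if self.voxels.ndim != 3:
            raise ValueError(f"CT voxels must be 3D, got shape {self.voxels.shape}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CT voxels contain non-finite values")
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class LabelVolume:
    """3D integer field; 0 = background, 1..n_classes-1 = distinct bones."""

    labels: np.ndarray
    n_classes: int
    spacing: Spacing = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.labels)
        if arr.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.round(arr)
            if np.max(np.abs(arr - rounded)) > LABEL_ROUND_TOL:
                raise ValueError("label values are not integers within tolerance")
            arr = rounded
        if arr.min() < 0 or arr.max() > self.n_classes - 1:
            raise ValueError(
                f"label values must lie in [0, {self.n_classes - 1}], "
                f"found range [{arr.min()}, {arr.max()}]"
            )
        self.labels = arr.astype(np.uint16)
        self.n_classes = int(self.n_classes)
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape

    def present_labels(self) -> np.ndarray:
        """Sorted array of nonzero labels that occur in the volume."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclass
class BinaryMask:
    """3D field in {0, 1}; 1 marks bone tissue (the y_bg/bt guide mask)."""

    mask: np.ndarray
    spacing: Spacing = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self):
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            rounded = np.round(arr)
            if np.max(np.abs(arr - rounded)) > LABEL_ROUND_TOL:
                raise ValueError("mask values are not integers within tolerance")
            arr = rounded
        vals = np.unique(arr)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"mask values must be 0 or 1, found {vals}")
        self.mask = arr.astype(np.uint8)
        self.spacing = _check_spacing(self.spacing)
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.mask.shape


Volume = Union[CTVolume, LabelVolume, BinaryMask]


def _grid(volume: Volume) -> np.ndarray:
    if isinstance(volume, CTVolume):
        return volume.voxels
    if isinstance(volume, LabelVolume):
        return volume.labels
    return volume.mask


def read_volume(path, kind: str, n_classes: int | None = None) -> Volume:
    """Read a NIfTI file as a CT volume, label volume or binary mask.

    Parameters
    ----------
    path
        Existing ``.nii`` / ``.nii.gz`` file.
    kind
        One of ``"ct"``, ``"labels"``, ``"mask"``.
    n_classes
        Declared class count for ``kind="labels"``; inferred as
        ``max(label) + 1`` when omitted.  Values outside ``[0, n_classes-1]``
        raise.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D image, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    affine = np.asarray(img.affine)
    if kind == "ct":
        return CTVolume(data.astype(np.float32), spacing, affine)
    if kind == "labels":
        if n_classes is None:
            n_classes = int(np.round(data.max())) + 1
        return LabelVolume(data, n_classes, spacing, affine)
    if kind == "mask":
        return BinaryMask(data, spacing, affine)
    raise ValueError(f"unknown kind {kind!r}")


def write_volume(volume: Volume, path) -> None:
    """Write a volume to NIfTI; ``read_volume`` inverts this exactly."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    data = _grid(volume)
    img = nib.Nifti1Image(data, volume.affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def _resample_grid(grid, in_spacing, target_spacing, order: int):
    in_shape = np.array(grid.shape, dtype=float)
    scale = np.array(in_spacing) / np.array(target_spacing)
    out_shape = np.maximum(1, np.round(in_shape * scale)).astype(int)
    # output voxel j samples input coordinate j * target / input per axis
    axes = [np.arange(n) * (t / s) for n, t, s in zip(out_shape, target_spacing, in_spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    if order == 0:
        # nearest neighbour, ties rounded toward the origin
        idx = []
        for c, n in zip(coords, grid.shape):
            f = np.floor(c)
            i = f + (c - f > 0.5)
            idx.append(np.clip(i.astype(int), 0, n - 1))
        return grid[tuple(idx)]
    return ndimage.map_coordinates(
        grid.astype(np.float32), np.stack(coords), order=order, mode="nearest"
    )


def resample(volume: Volume, target_spacing) -> Volume:
    """Resample to a new voxel spacing (e.g. the 2 mm isotropic grid).

    CT volumes are interpolated trilinearly; label volumes and masks use
    nearest-neighbour so no new label values can appear.
    """
    target_spacing = _check_spacing(target_spacing)
    if isinstance(volume, CTVolume):
        out = _resample_grid(volume.voxels, volume.spacing, target_spacing, order=1)
        return CTVolume(out, target_spacing)
    if isinstance(volume, LabelVolume):
        out = _resample_grid(volume.labels, volume.spacing, target_spacing, order=0)
        return LabelVolume(out, volume.n_classes, target_spacing)
    out = _resample_grid(volume.mask, volume.spacing, target_spacing, order=0)
    return BinaryMask(out, target_spacing)


def binarize_labels(labels: LabelVolume) -> BinaryMask:
    """Collapse a multi-class segmentation to bone-tissue vs background."""
    return BinaryMask(
        (labels.labels > 0).astype(np.uint8), labels.spacing, labels.affine
    )
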