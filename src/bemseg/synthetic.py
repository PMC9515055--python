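"""Procedural stick-figure skeletal CT phantoms with multi-class ground truth.

The generator produces randomized skeletons of 41 distinct bones laid out as
a human stick figure inside a 128 x 128 x 256 voxel grid, builds a
soft-tissue body from per-compartment convex hulls (head, torso, each limb),
and renders a CT with four Hounsfield-unit regimes (background, soft tissue,
cancellous bone interior, cortical bone shell) plus additive uniform noise.

Bones within a family (vertebrae, ribs, long-bone rods) deliberately share
geometry and differ chiefly in position, so that telling them apart requires
relative positioning rather than shape alone — the property that makes
distinct bone segmentation hard on real scans.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.morphology import convex_hull_image

from .volumes import BinaryMask, CTVolume, LabelVolume, write_volume

__all__ = [
    "BoneSpec",
    "AnatomyParams",
    "HUModel",
    "generate_skeleton",
    "generate_tissue_hull",
    "render_ct",
    "generate_volume",
    "generate_dataset",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass(frozen=True)
class BoneSpec:
    """One bone: a geometric solid with label id, shape family and pose.

    ``kind`` selects the rasterizer; ``geom`` holds its parameters in voxel
    coordinates:

    - ``sphere``: center (3,), r
    - ``capsule``: p0 (3,), p1 (3,), r  (rod with hemispherical caps)
    - ``vertebra``: center (3,), rx, ry, hz  (squashed elliptic cylinder)
    - ``arc``: center (x, y), R, theta0, theta1 (deg), z, r  (curved rib tube)
    - ``box``: lo (3,), hi (3,)  (axis-aligned cuboid, inclusive-exclusive)
    """

    label: int
    name: str
    family: str
    kind: str
    geom: dict
    compartment: str


@dataclass
class HUModel:
    """Hounsfield-unit regimes of the rendered phantom.

    Defaults are typical tissue values: air background -1000 HU, soft tissue
    +40 HU, cancellous (spongy) bone +300 HU, cortical shell +1200 HU, with
    i.i.d. uniform noise in [-noise_amplitude, +noise_amplitude].
    """

    hu_background: float = -1000.0
    hu_soft_tissue: float = 40.0
    hu_cancellous: float = 300.0
    hu_cortical: float = 1200.0
    noise_amplitude: float = 50.0

    def __post_init__(self):
        order = (
            self.hu_background,
            self.hu_soft_tissue,
            self.hu_cancellous,
            self.hu_cortical,
        )
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError("HU values must satisfy background < soft < cancellous < cortical")
        if self.noise_amplitude < 0:
            raise ValueError("noise_amplitude must be >= 0")


def _default_inventory() -> List[BoneSpec]:
    """The 41-bone stick-figure inventory for the 128 x 128 x 256 grid.

    Head sphere (1), 12 vertebrae (2-13), 8 rib pairs (14-21 left, 22-29
    right), 2 clavicles (30-31), humerus + forearm per arm (32-35), sternum
    plate (36), pelvis block (37), femur + lower leg per leg (38-41).
    """
    bones: List[BoneSpec] = []
    cx, cy = 64.0, 64.0
    bones.append(
        BoneSpec(1, "head", "sphere", "sphere",
                 dict(center=(cx, cy, 234.0), r=13.0), "head")
    )
    # vertebral column: identical squashed cylinders stacked along z
    for i in range(12):
        z = 134.0 + 7.0 * i
        bones.append(
            BoneSpec(2 + i, f"vertebra_{i + 1}", "vertebra", "vertebra",
                     dict(center=(cx, cy, z), rx=7.0, ry=6.0, hz=2.5), "torso")
        )
    # 8 rib pairs: curved tubes in the axial plane at vertebra levels 3..10
    for i in range(8):
        z = 134.0 + 7.0 * (i + 2)
        bones.append(
            BoneSpec(14 + i, f"rib_left_{i + 1}", "rib", "arc",
                     dict(center=(cx, cy), R=26.0, theta0=110.0, theta1=250.0,
                          z=z, r=2.0), "torso")
        )
    for i in range(8):
        z = 134.0 + 7.0 * (i + 2)
        bones.append(
            BoneSpec(22 + i, f"rib_right_{i + 1}", "rib", "arc",
                     dict(center=(cx, cy), R=26.0, theta0=-70.0, theta1=70.0,
                          z=z, r=2.0), "torso")
        )
    # clavicles
    bones.append(BoneSpec(30, "clavicle_left", "rod", "capsule",
                          dict(p0=(cx - 6, cy, 216.0), p1=(cx - 26, cy, 219.0), r=2.5),
                          "torso"))
    bones.append(BoneSpec(31, "clavicle_right", "rod", "capsule",
                          dict(p0=(cx + 6, cy, 216.0), p1=(cx + 26, cy, 219.0), r=2.5),
                          "torso"))
    # arms: humerus + forearm rods
    for side, sx, lab in (("left", -1.0, 32), ("right", +1.0, 34)):
        bones.append(BoneSpec(lab, f"humerus_{side}", "rod", "capsule",
                              dict(p0=(cx + sx * 30, cy, 214.0),
                                   p1=(cx + sx * 34, cy, 168.0), r=4.0),
                              f"arm_{side}"))
        bones.append(BoneSpec(lab + 1, f"forearm_{side}", "rod", "capsule",
                              dict(p0=(cx + sx * 34, cy, 166.0),
                                   p1=(cx + sx * 36, cy, 118.0), r=3.0),
                              f"arm_{side}"))
    bones.append(BoneSpec(36, "sternum", "plate", "box",
                          dict(lo=(58.0, 36.0, 150.0), hi=(70.0, 41.0, 200.0)), "torso"))
    bones.append(BoneSpec(37, "pelvis", "block", "box",
                          dict(lo=(46.0, 54.0, 108.0), hi=(82.0, 74.0, 126.0)), "torso"))
    # legs: femur + lower-leg rods
    for side, sx, lab in (("left", -1.0, 38), ("right", +1.0, 40)):
        bones.append(BoneSpec(lab, f"femur_{side}", "rod", "capsule",
                              dict(p0=(cx + sx * 12, cy, 112.0),
                                   p1=(cx + sx * 14, cy, 58.0), r=5.0),
                              f"leg_{side}"))
        bones.append(BoneSpec(lab + 1, f"lower_leg_{side}", "rod", "capsule",
                              dict(p0=(cx + sx * 14, cy, 56.0),
                                   p1=(cx + sx * 15, cy, 12.0), r=4.0),
                              f"leg_{side}"))
    assert [b.label for b in bones] == list(range(1, 42))
    return bones


def _mini_inventory() -> List[BoneSpec]:
    """A 7-bone miniature figure for a 32 x 32 x 64 grid (desk-scale runs)."""
    cx, cy = 16.0, 16.0
    bones = [
        BoneSpec(1, "head", "sphere", "sphere", dict(center=(cx, cy, 54.0), r=5.0), "head"),
        BoneSpec(2, "vertebra_1", "vertebra", "vertebra",
                 dict(center=(cx, cy, 46.0), rx=4.0, ry=3.5, hz=2.0), "torso"),
        BoneSpec(3, "vertebra_2", "vertebra", "vertebra",
                 dict(center=(cx, cy, 40.0), rx=4.0, ry=3.5, hz=2.0), "torso"),
        BoneSpec(4, "vertebra_3", "vertebra", "vertebra",
                 dict(center=(cx, cy, 34.0), rx=4.0, ry=3.5, hz=2.0), "torso"),
        BoneSpec(5, "pelvis", "block", "box",
                 dict(lo=(9.0, 12.0, 24.0), hi=(23.0, 20.0, 30.0)), "torso"),
        BoneSpec(6, "leg_left", "rod", "capsule",
                 dict(p0=(12.0, 16.0, 25.0), p1=(11.0, 16.0, 6.0), r=2.5), "leg_left"),
        BoneSpec(7, "leg_right", "rod", "capsule",
                 dict(p0=(20.0, 16.0, 25.0), p1=(21.0, 16.0, 6.0), r=2.5), "leg_right"),
    ]
    return bones


@dataclass
class AnatomyParams:
    """Randomized-skeleton parameters.

    ``jitter_translation`` is the half-range (voxels) of the uniform random
    per-bone shift; ``jitter_scale`` the half-range of the multiplicative
    size jitter.  ``seed`` fixes the whole skeleton.
    """

    volume_shape: Tuple[int, int, int] = (128, 128, 256)
    bone_inventory: List[BoneSpec] = field(default_factory=_default_inventory)
    jitter_translation: float = 2.0
    jitter_scale: float = 0.08
    seed: int = 0
    retry_budget: int = 10

    def __post_init__(self):
        if self.jitter_translation < 0 or self.jitter_scale < 0:
            raise ValueError("jitter ranges must be non-negative")
        labels = [b.label for b in self.bone_inventory]
        if sorted(labels) != list(range(1, len(labels) + 1)):
            raise ValueError("bone labels must be exactly 1..n_bones")

    @property
    def n_classes(self) -> int:
        return len(self.bone_inventory) + 1

    @property
    def compartments(self) -> Dict[str, List[int]]:
        comp: Dict[str, List[int]] = {}
        for b in self.bone_inventory:
            comp.setdefault(b.compartment, []).append(b.label)
        return comp

    @classmethod
    def mini(cls, seed: int = 0, **kw) -> "AnatomyParams":
        """Small phantom (7 bones, 32 x 32 x 64) for fast experiments."""
        return cls(volume_shape=(32, 32, 64), bone_inventory=_mini_inventory(),
                   jitter_translation=1.0, jitter_scale=0.05, seed=seed, **kw)


# ---------------------------------------------------------------------------
# rasterizers — each returns (slices, bool mask) or None if out of bounds
# ---------------------------------------------------------------------------

def _bbox_slices(lo, hi, shape):
    lo = np.floor(lo).astype(int)
    hi = np.ceil(hi).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(shape)):
        return None
    return tuple(slice(l, h) for l, h in zip(lo, hi))


def _grid_coords(slices):
    axes = [np.arange(s.start, s.stop, dtype=np.float64) for s in slices]
    return np.meshgrid(*axes, indexing="ij")


def _raster_sphere(geom, shape):
    c, r = np.asarray(geom["center"]), geom["r"]
    sl = _bbox_slices(c - r, c + r, shape)
    if sl is None:
        return None
    x, y, z = _grid_coords(sl)
    m = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= r**2
    return sl, m


def _raster_capsule(geom, shape):
    p0, p1, r = np.asarray(geom["p0"]), np.asarray(geom["p1"]), geom["r"]
    lo, hi = np.minimum(p0, p1) - r, np.maximum(p0, p1) + r
    sl = _bbox_slices(lo, hi, shape)
    if sl is None:
        return None
    x, y, z = _grid_coords(sl)
    d = p1 - p0
    L2 = float(d @ d)
    vx, vy, vz = x - p0[0], y - p0[1], z - p0[2]
    t = np.clip((vx * d[0] + vy * d[1] + vz * d[2]) / max(L2, 1e-12), 0.0, 1.0)
    m = (vx - t * d[0]) ** 2 + (vy - t * d[1]) ** 2 + (vz - t * d[2]) ** 2 <= r**2
    return sl, m


def _raster_vertebra(geom, shape):
    c = np.asarray(geom["center"])
    rx, ry, hz = geom["rx"], geom["ry"], geom["hz"]
    sl = _bbox_slices(c - (rx, ry, hz), c + (rx, ry, hz), shape)
    if sl is None:
        return None
    x, y, z = _grid_coords(sl)
    m = (((x - c[0]) / rx) ** 2 + ((y - c[1]) / ry) ** 2 <= 1.0) & (
        np.abs(z - c[2]) <= hz
    )
    return sl, m


def _raster_arc(geom, shape):
    cx, cy = geom["center"]
    R, r, z0 = geom["R"], geom["r"], geom["z"]
    t0, t1 = np.deg2rad(geom["theta0"]), np.deg2rad(geom["theta1"])
    n = max(16, int(np.ceil(abs(t1 - t0) * R / 0.5)))
    th = np.linspace(t0, t1, n)
    pts = np.stack([cx + R * np.cos(th), cy + R * np.sin(th), np.full(n, z0)], axis=1)
    lo, hi = pts.min(axis=0) - r, pts.max(axis=0) + r
    sl = _bbox_slices(lo, hi, shape)
    if sl is None:
        return None
    x, y, z = _grid_coords(sl)
    vox = np.stack([x, y, z], axis=-1)  # (..., 3)
    d2 = np.full(x.shape, np.inf)
    for p in pts:  # dense sampling: spacing ~0.5 voxel
        d2 = np.minimum(d2, np.sum((vox - p) ** 2, axis=-1))
    m = d2 <= r**2
    return sl, m


def _raster_box(geom, shape):
    lo, hi = np.asarray(geom["lo"]), np.asarray(geom["hi"])
    sl = _bbox_slices(lo, hi - 1, shape)
    if sl is None:
        return None
    m = np.ones([s.stop - s.start for s in sl], dtype=bool)
    return sl, m


_RASTERIZERS = {
    "sphere": _raster_sphere,
    "capsule": _raster_capsule,
    "vertebra": _raster_vertebra,
    "arc": _raster_arc,
    "box": _raster_box,
}


def _jitter_geom(spec: BoneSpec, rng: np.random.Generator, dt: float, ds: float) -> dict:
    shift = rng.uniform(-dt, dt, size=3)
    scale = 1.0 + rng.uniform(-ds, ds)
    g = dict(spec.geom)
    if spec.kind == "sphere":
        g["center"] = tuple(np.asarray(g["center"]) + shift)
        g["r"] = g["r"] * scale
    elif spec.kind == "capsule":
        g["p0"] = tuple(np.asarray(g["p0"]) + shift)
        g["p1"] = tuple(np.asarray(g["p1"]) + shift)
        g["r"] = g["r"] * scale
    elif spec.kind == "vertebra":
        g["center"] = tuple(np.asarray(g["center"]) + shift)
        g["rx"], g["ry"], g["hz"] = g["rx"] * scale, g["ry"] * scale, g["hz"] * scale
    elif spec.kind == "arc":
        g["center"] = (g["center"][0] + shift[0], g["center"][1] + shift[1])
        g["z"] = g["z"] + shift[2]
        g["R"], g["r"] = g["R"] * scale, g["r"] * scale
    elif spec.kind == "box":
        c = (np.asarray(g["lo"]) + np.asarray(g["hi"])) / 2.0
        half = (np.asarray(g["hi"]) - np.asarray(g["lo"])) / 2.0 * scale
        g["lo"], g["hi"] = tuple(c + shift - half), tuple(c + shift + half)
    return g


def _is_connected(mask: np.ndarray) -> bool:
    if not mask.any():
        return False
    _, n = ndimage.label(mask, structure=_STRUCT26)
    return n == 1


def generate_skeleton(params: AnatomyParams) -> LabelVolume:
    """Rasterize the randomized stick-figure skeleton.

    Bones are drawn in label order; where two solids would overlap (e.g. a
    femur head inside the pelvis block) the earlier bone wins, which keeps
    every bone a single connected component.  A draw whose jitter pushes a
    bone outside the volume, erases it completely, or disconnects it is
    rejected and retried with fresh jitter up to ``params.retry_budget``
    times.
    """
    rng = np.random.default_rng(np.random.SeedSequence(params.seed))
    shape = tuple(params.volume_shape)
    for _attempt in range(params.retry_budget):
        vol = np.zeros(shape, dtype=np.uint16)
        ok = True
        for spec in params.bone_inventory:
            g = _jitter_geom(spec, rng, params.jitter_translation, params.jitter_scale)
            out = _RASTERIZERS[spec.kind](g, shape)
            if out is None:  # bone would leave the volume
                ok = False
                break
            sl, m = out
            region = vol[sl]
            write = m & (region == 0)
            if not write.any() or not _is_connected(write):
                ok = False
                break
            region[write] = spec.label
        if ok:
            return LabelVolume(vol, n_classes=params.n_classes)
    raise RuntimeError(
        f"could not place all bones inside the volume in {params.retry_budget} attempts; "
        "reduce jitter or enlarge the volume"
    )


def generate_tissue_hull(
    labels: LabelVolume, compartments: Dict[str, Sequence[int]] | None = None
) -> BinaryMask:
    """Soft-tissue body mask: union of per-compartment bone convex hulls.

    Hulls are taken per body compartment (head, torso, each limb) rather
    than globally, so the space between the limbs stays background.  Every
    bone voxel lies inside the returned mask.
    """
    if compartments is None:
        compartments = {"body": list(range(1, labels.n_classes))}
    arr = labels.labels
    out = np.zeros(arr.shape, dtype=bool)
    for name, labs in compartments.items():
        m = np.isin(arr, np.asarray(labs, dtype=arr.dtype))
        if not m.any():
            raise ValueError(f"compartment {name!r} contains no bone voxels")
        # hull within a one-voxel-padded bounding box for speed
        sl = ndimage.find_objects(m.astype(np.uint8))[0]
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, arr.shape)
        )
        out[sl] |= convex_hull_image(m[sl])
    return BinaryMask(out.astype(np.uint8), labels.spacing, labels.affine)


def render_ct(
    labels: LabelVolume,
    hull: BinaryMask,
    hu: HUModel | None = None,
    seed: int = 0,
) -> CTVolume:
    """Render Hounsfield units from the skeleton and soft-tissue hull.

    Voxels outside the hull are background, hull voxels without bone are
    soft tissue, bone interiors are cancellous, and the one-voxel cortical
    shell (bone voxels with a 6-neighbour outside their own bone) is
    cortical.  I.i.d. uniform noise in +-noise_amplitude is added on top.
    """
    if hu is None:
        hu = HUModel()
    if labels.shape != hull.shape:
        raise ValueError("labels and hull shapes differ")
    arr = labels.labels
    bone = arr > 0
    ct = np.full(arr.shape, hu.hu_background, dtype=np.float32)
    ct[(hull.mask == 1) & ~bone] = hu.hu_soft_tissue
    ct[bone] = hu.hu_cancellous
    # cortical shell per bone, inside a padded bounding box
    objects = ndimage.find_objects(arr)
    for lab, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        sl = tuple(
            slice(max(s.start - 1, 0), min(s.stop + 1, n))
            for s, n in zip(sl, arr.shape)
        )
        m = arr[sl] == lab
        shell = m & ~ndimage.binary_erosion(m, structure=_STRUCT6)
        ct[sl][shell] = hu.hu_cortical
    if hu.noise_amplitude > 0:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        ct += rng.uniform(
            -hu.noise_amplitude, hu.noise_amplitude, size=ct.shape
        ).astype(np.float32)
    return CTVolume(ct, labels.spacing, labels.affine)


def generate_volume(
    params: AnatomyParams, hu: HUModel | None = None
) -> Tuple[CTVolume, LabelVolume]:
    """Generate one (CT, labels) phantom pair from ``params.seed``."""
    labels = generate_skeleton(params)
    hullmask = generate_tissue_hull(labels, params.compartments)
    ct = render_ct(labels, hullmask, hu, seed=params.seed)
    return ct, labels


def generate_dataset(
    out_dir,
    n_volumes: int = 50,
    split: Tuple[int, int, int] = (17, 7, 26),
    seed: int = 0,
    params: AnatomyParams | None = None,
    hu: HUModel | None = None,
    compress: bool = True,
) -> pd.DataFrame:
    """Write ``n_volumes`` phantom pairs plus a manifest CSV.

    The default configuration matches the public-dataset regime: 50 scans of
    128 x 128 x 256 voxels with a 17/7/26 train/validation/test split.
    Per-volume seeds are derived from ``(seed, index)`` with a counter-based
    scheme, so any volume regenerates identically regardless of order.
    """
    if sum(split) != n_volumes:
        raise ValueError(f"split {split} does not sum to n_volumes={n_volumes}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base = params if params is not None else AnatomyParams()
    splits = ["train"] * split[0] + ["val"] * split[1] + ["test"] * split[2]
    ext = ".nii.gz" if compress else ".nii"
    rows = []
    for i in range(n_volumes):
        vol_seed = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31)
        p = dataclasses.replace(base, seed=vol_seed)
        ct, labels = generate_volume(p, hu)
        ct_path = out_dir / f"case_{i:04d}_ct{ext}"
        seg_path = out_dir / f"case_{i:04d}_seg{ext}"
        write_volume(ct, ct_path)
        write_volume(labels, seg_path)
        rows.append(
            dict(case_id=f"case_{i:04d}", ct_path=str(ct_path),
                 seg_path=str(seg_path), split=splits[i])
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
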