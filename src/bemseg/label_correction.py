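"""Connected-component label correction.

Segmentations of elongated bones (ribs especially) often come out split
into several components carrying different labels.  Within hand-chosen sets
of easily confused classes, this module finds each class's largest connected
component (its *anchor*) and relabels smaller components of *other* classes
in the set to the label of an adjacent anchor.  Fragments touching no anchor
are left in place rather than deleted, so the foreground voxel set is
conserved exactly.

A per-class cap ``u`` on the number of components considered bounds the
pairwise adjacency work by ``|L|^2 * u`` per set; sets are independent and
processed one after the other (they could run in parallel).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .volumes import LabelVolume

__all__ = [
    "ConfusionSetConfig",
    "Component",
    "ComponentTable",
    "find_components",
    "correct_labels",
    "default_confusion_sets",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_STRUCT26 = ndimage.generate_binary_structure(3, 3)


@dataclass
class ConfusionSetConfig:
    """Label sets processed jointly, plus the per-class component cap u."""

    sets: List[List[int]]
    cap: int = 100
    connectivity: int = 26

    def __post_init__(self):
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        if self.connectivity not in (6, 26):
            raise ValueError("connectivity must be 6 or 26")
        seen: set = set()
        for L in self.sets:
            if any(l < 1 for l in L):
                raise ValueError("confusion sets may only contain labels >= 1")
            if seen & set(L):
                raise ValueError("confusion sets must be pairwise disjoint")
            seen |= set(L)

    @property
    def structure(self) -> np.ndarray:
        return _STRUCT26 if self.connectivity == 26 else _STRUCT6


@dataclass
class Component:
    label: int
    voxels: Tuple[np.ndarray, ...]  # index arrays into the volume
    size: int
    is_anchor: bool = False


@dataclass
class ComponentTable:
    """Per class: components sorted by size (largest first, capped at u)."""

    components: Dict[int, List[Component]] = field(default_factory=dict)

    def anchor(self, label: int) -> Component | None:
        comps = self.components.get(label, [])
        return comps[0] if comps else None


def find_components(
    labels: LabelVolume, L: Sequence[int], cap: int = 100, connectivity: int = 26
) -> ComponentTable:
    """Connected components of every class in ``L``.

    Components are sorted by size descending (ties broken by smallest
    flattened voxel index) and truncated to the ``cap`` largest; the largest
    component of each nonempty class is flagged as the anchor.
    """
    struct = _STRUCT26 if connectivity == 26 else _STRUCT6
    arr = labels.labels
    table = ComponentTable()
    for lab in L:
        mask = arr == lab
        table.components[lab] = []
        if not mask.any():
            continue
        cc, n = ndimage.label(mask, structure=struct)
        order = []
        for ci in range(1, n + 1):
            vox = np.nonzero(cc == ci)
            size = len(vox[0])
            first = int(np.ravel_multi_index((vox[0][0], vox[1][0], vox[2][0]), arr.shape))
            order.append((-size, first, vox, size))
        order.sort(key=lambda t: (t[0], t[1]))
        comps = [
            Component(lab, vox, size, is_anchor=(i == 0))
            for i, (_, _, vox, size) in enumerate(order[:cap])
        ]
        table.components[lab] = comps
    return table


def _contact_pairs(frag_vox, anchor_mask_padded: np.ndarray, struct: np.ndarray) -> int:
    """Number of neighbouring voxel pairs between a fragment and an anchor.

    ``anchor_mask_padded`` is the anchor indicator padded by one voxel so
    neighbourhood lookups never leave the array.
    """
    offs = np.argwhere(struct) - 1
    offs = offs[np.any(offs != 0, axis=1)]
    fx, fy, fz = (v + 1 for v in frag_vox)  # shift into padded coords
    total = 0
    for ox, oy, oz in offs:
        total += int(anchor_mask_padded[fx + ox, fy + oy, fz + oz].sum())
    return total


def correct_labels(
    labels: LabelVolume, cfg: ConfusionSetConfig, return_stats: bool = False
):
    """Reassign stray components to adjacent anchors, set by set.

    For each confusion set the reassignment is computed from the *input*
    labeling and applied atomically: a non-anchor component whose voxels
    touch the anchor of a different class in the set takes that anchor's
    label (strongest contact wins; ties go to the lowest class id).
    Anchors, classes outside every set, and the foreground/background
    partition are never changed.

    With ``return_stats`` the number of fragment-vs-anchor adjacency tests
    per set is reported alongside (bounded by ``|L|^2 * cap``).
    """
    arr = labels.labels.copy()
    struct = cfg.structure
    stats = {"adjacency_tests_per_set": [], "reassigned_components": 0}
    for L in cfg.sets:
        table = find_components(labels, L, cfg.cap, cfg.connectivity)
        anchors = {}
        for lab in L:
            a = table.anchor(lab)
            if a is not None:
                pad = np.zeros(tuple(s + 2 for s in arr.shape), dtype=bool)
                pad[1:-1, 1:-1, 1:-1][a.voxels] = True
                anchors[lab] = pad
        tests = 0
        moves = []
        for lab in L:
            for comp in table.components.get(lab, [])[1:]:  # skip the anchor
                best = None  # (-contact, class id)
                for other, amask in anchors.items():
                    if other == lab:
                        continue
                    tests += 1
                    contact = _contact_pairs(comp.voxels, amask, struct)
                    if contact > 0:
                        cand = (-contact, other)
                        if best is None or cand < best:
                            best = cand
                if best is not None:
                    moves.append((comp, best[1]))
        for comp, new_label in moves:
            arr[comp.voxels] = new_label
        stats["adjacency_tests_per_set"].append(tests)
        stats["reassigned_components"] += len(moves)
        assert tests <= len(L) ** 2 * cfg.cap
    out = LabelVolume(arr, labels.n_classes, labels.spacing, labels.affine)
    if return_stats:
        return out, stats
    return out


def default_confusion_sets(n_classes: int, cap: int = 100) -> ConfusionSetConfig:
    """Editable default confusion sets.

    For the 42-class synthetic skeleton the sets follow the bone families
    of the generator (vertebral column, left/right rib cage, shoulder
    girdle + arms, pelvis + legs).  For other class counts, consecutive
    label runs of size 4-12 are grouped — a stand-in for anatomy-derived
    sets, which should be edited to match the label scheme at hand.
    """
    if n_classes == 42:
        sets = [
            list(range(2, 14)),            # 12 vertebrae
            list(range(14, 22)),           # left ribs
            list(range(22, 30)),           # right ribs
            [30, 32, 33, 36],              # left shoulder girdle + arm (+sternum)
            [31, 34, 35, 1],               # right shoulder girdle + arm (+head)
            [37, 38, 39, 40, 41],          # pelvis + legs
        ]
        return ConfusionSetConfig(sets=sets, cap=cap)
    if n_classes == 8:  # mini 7-bone phantom
        return ConfusionSetConfig(sets=[[2, 3, 4, 5], [1, 6, 7]], cap=cap)
    sets = []
    lab = 1
    while lab < n_classes:
        run = min(8, n_classes - lab)
        if run < 4 and sets:
            sets[-1].extend(range(lab, n_classes))
            break
        sets.append(list(range(lab, lab + run)))
        lab += run
    return ConfusionSetConfig(sets=sets, cap=cap)
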