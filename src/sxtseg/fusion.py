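"""The three fusion algorithms of the segmentation pipeline.

1. **Multi-view semantic fusion** — per-voxel majority voting over the
   three single-view 3D masks reconstructed from X, Y and Z slice
   predictions: a voxel is foreground iff at least 2 of 3 views agree.
2. **2D -> 3D instance linking** — 2D vesicle instances on adjacent
   slices are chained into one 3D instance when their footprint IoU
   exceeds 0.5; chains propagate transitively along the slicing axis.
3. **Priority merging** — per-class masks are flattened into a single
   categorical scene under the fixed priority
   vesicle > nucleus > mitochondria > cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

from .volume import BinaryMask, CellScene, InstanceMap, SCENE_CODES

__all__ = [
    "ViewTriplet",
    "fuse_multiview",
    "iou",
    "link_instances",
    "fuse_priority",
]

ArrayLike = Union[np.ndarray, BinaryMask]


def _as_bool(mask: ArrayLike) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.data
    return np.asarray(mask).astype(bool)


@dataclass
class ViewTriplet:
    """Three same-shape binary masks of one semantic class, each
    reconstructed by stacking the 2D predictions of one viewing axis."""

    mask_x: BinaryMask
    mask_y: BinaryMask
    mask_z: BinaryMask

    def __post_init__(self) -> None:
        shapes = {self.mask_x.shape, self.mask_y.shape, self.mask_z.shape}
        if len(shapes) > 1:
            raise ValueError(f"view masks have different shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask_x.shape


def fuse_multiview(views: ViewTriplet) -> BinaryMask:
    """Majority-vote fusion of the three per-axis masks.

    A voxel is set iff at least two of the three views predict it.  The
    result always lies between the intersection and the union of the
    views, and unanimity is preserved exactly.
    """
    votes = (
        views.mask_x.data.astype(np.uint8)
        + views.mask_y.data.astype(np.uint8)
        + views.mask_z.data.astype(np.uint8)
    )
    return BinaryMask(votes >= 2, class_name=views.mask_x.class_name)


def iou(mask_a: ArrayLike, mask_b: ArrayLike) -> float:
    """Intersection over union of two binary regions (2D or 3D).

    Raises if both regions are empty — the ratio is undefined there.
    """
    a, b = _as_bool(mask_a), _as_bool(mask_b)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    inter = np.count_nonzero(a & b)
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("IoU is undefined for two empty masks")
    return inter / union


def _pairwise_overlaps(prev: np.ndarray, cur: np.ndarray):
    """IoU of every (prev-label, cur-label) pair with nonzero footprint
    overlap, from a joint label histogram."""
    both = (prev > 0) & (cur > 0)
    prev_areas = np.bincount(prev.ravel())
    cur_areas = np.bincount(cur.ravel())
    if not both.any():
        return []
    pairs, inters = np.unique(
        np.stack([prev[both], cur[both]]), axis=1, return_counts=True
    )
    out = []
    for (p, c), inter in zip(pairs.T, inters):
        union = prev_areas[p] + cur_areas[c] - inter
        out.append((inter / union, int(p), int(c)))
    return out


def link_instances(
    slices: Sequence[np.ndarray], threshold: float = 0.5
) -> InstanceMap:
    """Chain per-slice 2D instances into 3D instances along the stack axis.

    Two instances on adjacent slices are joined when the IoU of their
    full 2D footprints is strictly greater than ``threshold`` (0.5 by
    default); chains propagate transitively.  When one instance exceeds
    the threshold against several candidates it links to the highest-IoU
    candidate only (ties broken toward the lower label), keeping the
    chaining one-to-one.  Instances missing from an intermediate slice
    are not bridged.  Output labels are contiguous 1..n.
    """
    slices = [np.asarray(s) for s in slices]
    if not slices:
        raise ValueError("link_instances requires at least one slice")
    shape2d = slices[0].shape
    for i, s in enumerate(slices):
        if s.ndim != 2 or s.shape != shape2d:
            raise ValueError(f"slice {i} shape {s.shape} != {shape2d}")
        if s.min() < 0:
            raise ValueError("instance labels must be non-negative")
    out = np.zeros((len(slices),) + shape2d, dtype=np.int32)
    next_label = 1
    prev_assign: dict[int, int] = {}  # 2D label on previous slice -> 3D label
    prev = None
    for i, cur in enumerate(slices):
        cur_labels = np.unique(cur)
        cur_labels = cur_labels[cur_labels > 0]
        assign: dict[int, int] = {}
        if prev is not None and cur_labels.size:
            candidates = [
                t for t in _pairwise_overlaps(prev.astype(np.int64), cur.astype(np.int64))
                if t[0] > threshold
            ]
            # greedy best-IoU one-to-one matching; ties toward lower labels
            candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
            used_prev: set[int] = set()
            for score, p, c in candidates:
                if c in assign or p in used_prev:
                    continue
                assign[c] = prev_assign[p]
                used_prev.add(p)
        for lab in cur_labels:
            if int(lab) not in assign:
                assign[int(lab)] = next_label
                next_label += 1
        for lab, lab3d in assign.items():
            out[i][cur == lab] = lab3d
        prev, prev_assign = cur, assign
    return InstanceMap.from_labels(out)


def fuse_priority(
    cell: BinaryMask,
    nucleus: BinaryMask,
    mito: BinaryMask,
    vesicles: InstanceMap,
) -> CellScene:
    """Merge per-class masks into one scene under the priority
    vesicle > nucleus > mitochondria > cell.

    Every voxel receives the highest-priority class claiming it; vesicle
    voxels are never overwritten, voxels claimed only by the cell mask
    become cytoplasm, and unclaimed voxels are outside.  Nucleus or
    mitochondria voxels falling outside the cell mask keep their
    organelle code (the priority rule applied literally); such voxels
    are surfaced by :func:`priority_qc`.
    """
    shapes = {cell.shape, nucleus.shape, mito.shape, vesicles.shape}
    if len(shapes) > 1:
        raise ValueError(f"mask shapes differ: {shapes}")
    scene = np.zeros(cell.shape, dtype=np.uint8)
    scene[cell.data] = SCENE_CODES["cytoplasm"]
    scene[mito.data] = SCENE_CODES["mitochondria"]
    scene[nucleus.data] = SCENE_CODES["nucleus"]
    scene[vesicles.data > 0] = SCENE_CODES["vesicle"]
    return CellScene(scene)


def priority_qc(
    cell: BinaryMask, nucleus: BinaryMask, mito: BinaryMask, vesicles: InstanceMap
) -> dict[str, int]:
    """Count organelle voxels lying outside the cell mask — a consistency
    diagnostic for upstream segmentations."""
    outside = ~cell.data
    return {
        "nucleus_outside_cell": int(np.count_nonzero(nucleus.data & outside)),
        "mitochondria_outside_cell": int(np.count_nonzero(mito.data & outside)),
        "vesicle_outside_cell": int(np.count_nonzero((vesicles.data > 0) & outside)),
    }
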