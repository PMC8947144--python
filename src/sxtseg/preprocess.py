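"""Volume canonicalization and 2D slice/patch plumbing.

Tomograms arrive cropped to the capillary region and are resized to the
canonical grid (280, 480, 320).  Semantic networks consume per-axis 2D
slice stacks; the instance network consumes overlapping 2D patches of
about 150 x 50 pixels with >= 30 % overlap.  This module provides the
lossless conversions between those representations and the score-based
merge that resolves patch overlaps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .volume import Volume

__all__ = [
    "CANONICAL_SHAPE",
    "DEFAULT_PATCH_SHAPE",
    "DEFAULT_PATCH_OVERLAP",
    "SliceStack",
    "Patch",
    "PatchGrid",
    "crop_to_box",
    "resize_to_canonical",
    "slice_along_axis",
    "stack_to_volume",
    "split_patches",
    "merge_patches",
]

#: Canonical (width, height, depth) of a preprocessed tomogram.
CANONICAL_SHAPE = (280, 480, 320)
DEFAULT_PATCH_SHAPE = (150, 50)
DEFAULT_PATCH_OVERLAP = 0.30

_AXES = {"X": 0, "Y": 1, "Z": 2}


@dataclass
class SliceStack:
    """An ordered stack of 2D slices taken along one axis of a volume."""

    axis: str
    slices: list[np.ndarray]
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.axis not in _AXES:
            raise ValueError(f"unknown axis {self.axis!r}; expected X, Y or Z")
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"slices have inconsistent shapes: {shapes}")

    @property
    def n_slices(self) -> int:
        return len(self.slices)


@dataclass
class Patch:
    """One tile of a 2D image: origin (row, col), pixel data, and an
    optional per-pixel confidence grid used when merging."""

    origin: tuple[int, int]
    data: np.ndarray
    scores: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.scores is not None and self.scores.shape != self.data.shape:
            raise ValueError("patch scores must match patch data shape")


@dataclass
class PatchGrid:
    source_shape: tuple[int, int]
    patches: list[Patch]


def crop_to_box(vol: Volume, box: Sequence[tuple[int, int]]) -> Volume:
    """Crop a volume to a half-open index box ``[(x0,x1),(y0,y1),(z0,z1)]``.

    The capillary walls that bound the usable field of view are supplied
    as an explicit box; values are copied unchanged.
    """
    if len(box) != 3:
        raise ValueError("box must give one (start, stop) pair per axis")
    slices = []
    for axis, (start, stop) in enumerate(box):
        extent = vol.shape[axis]
        if not (0 <= start < stop <= extent):
            raise ValueError(
                f"box [{start}, {stop}) invalid for axis {axis} of extent {extent}"
            )
        slices.append(slice(start, stop))
    return Volume(vol.data[tuple(slices)].copy(), voxel_size=vol.voxel_size)


def resize_to_canonical(
    vol: Volume,
    target: tuple[int, int, int] = CANONICAL_SHAPE,
    kind: str = "intensity",
) -> Volume:
    """Resize a volume to the canonical grid.

    ``kind='intensity'`` uses trilinear interpolation; ``kind='label'``
    uses nearest-neighbor so no new label values are introduced.
    """
    if kind not in ("intensity", "label"):
        raise ValueError(f"kind must be 'intensity' or 'label', got {kind!r}")
    if len(target) != 3 or min(target) < 1:
        raise ValueError(f"target shape must be 3 positive integers, got {target}")
    if tuple(vol.shape) == tuple(target):
        return Volume(vol.data.copy(), voxel_size=vol.voxel_size)
    order = 1 if kind == "intensity" else 0
    out = _sk_resize(
        vol.data,
        target,
        order=order,
        preserve_range=True,
        anti_aliasing=False,
        mode="edge",
    )
    return Volume(out.astype(np.float32), voxel_size=vol.voxel_size)


def slice_along_axis(vol: Volume, axis: str) -> SliceStack:
    """Decompose a volume into 2D slices along X, Y or Z.

    A canonical (280, 480, 320) volume yields 280 slices of shape
    (480, 320) along X, 480 along Y and 320 along Z.
    """
    if axis not in _AXES:
        raise ValueError(f"unknown axis {axis!r}; expected X, Y or Z")
    moved = np.moveaxis(vol.data, _AXES[axis], 0)
    return SliceStack(axis=axis, slices=[s.copy() for s in moved], voxel_size=vol.voxel_size)


def stack_to_volume(stack: SliceStack) -> Volume:
    """Reassemble a SliceStack into a Volume; exact inverse of
    :func:`slice_along_axis` for every axis."""
    if not stack.slices:
        raise ValueError("cannot reassemble an empty slice stack")
    data = np.moveaxis(np.stack(stack.slices, axis=0), 0, _AXES[stack.axis])
    return Volume(data, voxel_size=stack.voxel_size)


def _tile_origins(extent: int, patch: int, overlap: float) -> list[int]:
    """Regular tiling origins with stride floor(patch*(1-overlap)); the
    final patch is snapped to the border so coverage is complete and the
    requested overlap is a minimum."""
    if patch >= extent:
        return [0]
    stride = max(1, math.floor(patch * (1.0 - overlap)))
    origins = list(range(0, extent - patch, stride))
    origins.append(extent - patch)
    return sorted(set(origins))


def split_patches(
    img: np.ndarray,
    patch_shape: tuple[int, int] = DEFAULT_PATCH_SHAPE,
    min_overlap: float = DEFAULT_PATCH_OVERLAP,
) -> PatchGrid:
    """Tile a 2D image into overlapping patches on a regular grid.

    Every pixel is covered by at least one patch and consecutive patches
    overlap by at least ``min_overlap`` of the patch extent along each
    tiled dimension.  Patches larger than the image are clipped to the
    image, never padded.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("split_patches expects a 2D image")
    if min(patch_shape) < 1:
        raise ValueError(f"patch shape must be positive, got {patch_shape}")
    if not (0.0 <= min_overlap < 1.0):
        raise ValueError(f"overlap must lie in [0, 1), got {min_overlap}")
    h, w = img.shape
    ph, pw = min(patch_shape[0], h), min(patch_shape[1], w)
    patches = [
        Patch(origin=(r, c), data=img[r : r + ph, c : c + pw].copy())
        for r in _tile_origins(h, ph, min_overlap)
        for c in _tile_origins(w, pw, min_overlap)
    ]
    return PatchGrid(source_shape=(h, w), patches=patches)


def merge_patches(grid: PatchGrid) -> tuple[np.ndarray, np.ndarray]:
    """Fuse scored patches back into one image.

    In overlap regions the prediction with the higher per-pixel score is
    retained; ties go to the patch that appears earlier in the grid, and
    pixels covered by a single patch pass through unchanged.  Every pixel
    of the source shape must be covered by at least one patch.
    """
    if not grid.patches:
        raise ValueError("cannot merge an empty patch grid")
    for p in grid.patches:
        if p.scores is None:
            raise ValueError("merge_patches requires a score grid on every patch")
    out = np.zeros(grid.source_shape, dtype=grid.patches[0].data.dtype)
    best = np.full(grid.source_shape, -np.inf, dtype=np.float64)
    for p in grid.patches:
        r, c = p.origin
        ph, pw = p.data.shape
        if r < 0 or c < 0 or r + ph > grid.source_shape[0] or c + pw > grid.source_shape[1]:
            raise ValueError(f"patch at {p.origin} exceeds source shape {grid.source_shape}")
        window = best[r : r + ph, c : c + pw]
        take = p.scores > window  # strict: earlier patch wins ties
        out[r : r + ph, c : c + pw][take] = p.data[take]
        window[take] = p.scores[take]
    if np.any(np.isneginf(best)):
        raise ValueError("patches do not cover the source shape")
    return out, best
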