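"""Synthetic single-cell phantoms and prediction degradation.

SXT tomograms of INS-1E beta cells are not publicly deposited, so every
pipeline stage is exercised on synthetic phantoms that reproduce the
statistical structure of the real data: one ellipsoidal cell, one
off-center ellipsoidal nucleus, dispersed elongated mitochondria whose
LAC sits only ~10 % above the cytosol (the low contrast that makes
mitochondria the hardest class), and spherical dense-core insulin
vesicles whose LAC rises from ~0.35 at the rim to ~0.55 at the core —
inside the 0.3–0.6 range characteristic of insulin granules.

The module also provides a prediction-degradation simulator (voxel
drop-out, speckle, boundary jitter) to test the multi-view voting
fusion, and a naive threshold-based segmentation backend so the whole
pipeline can run end-to-end without any trained network.

All randomness flows through one explicitly passed numpy Generator, so
a phantom is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .fusion import ViewTriplet
from .volume import BinaryMask, InstanceMap, Volume

__all__ = [
    "PhantomSpec",
    "Phantom",
    "DEFAULT_LAC_LEVELS",
    "DEFAULT_THRESHOLDS",
    "generate_phantom",
    "place_centers_uniform",
    "degrade_views",
    "threshold_segment",
]

#: Mean LAC per region.  Cytosol 0.30 with mitochondria at 0.33 gives the
#: ~1.1 mitochondria/cytosol contrast ratio of real tomograms; vesicles
#: ramp from rim 0.35 to core 0.55.  Nucleus and background are chosen
#: below the cytosol, as in real reconstructions.
DEFAULT_LAC_LEVELS = {
    "outside": 0.10,
    "cytoplasm": 0.30,
    "nucleus": 0.25,
    "mitochondria": 0.33,
    "vesicle_rim": 0.35,
    "vesicle_core": 0.55,
}

#: LAC cutoffs for the naive threshold backend, placed between the
#: phantom levels: cell = everything above the background/nucleus gap,
#: nucleus = the low-LAC interior, mitochondria and vesicles above the
#: cytosol.
DEFAULT_THRESHOLDS = {
    "cell": 0.175,
    "nucleus": 0.275,
    "mitochondria": 0.315,
    "vesicle": 0.40,
}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic cell.

    The default shape (140, 240, 160) is half the canonical tomogram
    grid, which keeps whole-phantom tests fast while preserving the
    geometry.  ``nucleus_radius_frac`` scales the nucleus semi-axes
    relative to the cell's; vesicle radii are drawn uniformly from
    ``vesicle_radius_range`` (voxels).
    """

    shape: tuple[int, int, int] = (140, 240, 160)
    nucleus_radius_frac: float = 0.45
    n_mito: int = 20
    n_vesicles: int = 150
    vesicle_radius_range: tuple[float, float] = (3.0, 6.0)
    lac_levels: dict = field(default_factory=lambda: dict(DEFAULT_LAC_LEVELS))
    noise_sd: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.nucleus_radius_frac < 1.0):
            raise ValueError("nucleus_radius_frac must lie in (0, 1)")
        if self.lac_levels["mitochondria"] <= self.lac_levels["cytoplasm"]:
            raise ValueError("mitochondria LAC must exceed cytoplasm LAC")
        if self.lac_levels["vesicle_rim"] <= self.lac_levels["cytoplasm"]:
            raise ValueError("vesicle rim LAC must exceed cytoplasm LAC")
        if self.n_mito < 0 or self.n_vesicles < 0:
            raise ValueError("organelle counts must be non-negative")


@dataclass
class Phantom:
    """A generated phantom: the noisy LAC volume plus its ground truth."""

    volume: Volume
    gt_cell: BinaryMask
    gt_nucleus: BinaryMask
    gt_mito: BinaryMask
    gt_vesicles: InstanceMap
    placement_log: list[dict]


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _rotated_ellipsoid(shape, center, direction, long_axis, short_axis) -> np.ndarray:
    """Ellipsoid with its long axis along ``direction`` — a simple
    tubular mitochondrion."""
    direction = np.asarray(direction, dtype=float)
    direction /= np.linalg.norm(direction)
    lo = np.maximum(np.floor(np.asarray(center) - long_axis - 1), 0).astype(int)
    hi = np.minimum(np.ceil(np.asarray(center) + long_axis + 2), shape).astype(int)
    out = np.zeros(shape, dtype=bool)
    if np.any(lo >= hi):
        return out
    grids = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
    rel = np.stack([g - c for g, c in zip(grids, center)], axis=-1)
    axial = rel @ direction
    radial_sq = np.maximum(np.sum(rel**2, axis=-1) - axial**2, 0.0)
    inside = (axial / long_axis) ** 2 + radial_sq / short_axis**2 <= 1.0
    out[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return out


def place_centers_uniform(
    n: int,
    region: Union[BinaryMask, np.ndarray],
    min_sep: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> list[np.ndarray]:
    """Draw ``n`` centers uniformly over the voxels of ``region``.

    With ``min_sep > 0`` candidates closer than ``min_sep`` to an
    accepted center are rejected; an infeasible packing raises after the
    candidate pool is exhausted.  Reproducible through ``rng`` or
    ``seed``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    region_arr = region.data if isinstance(region, BinaryMask) else np.asarray(region)
    region_arr = region_arr.astype(bool)
    if n == 0:
        return []
    coords = np.argwhere(region_arr)
    if coords.shape[0] == 0:
        raise ValueError("placement region is empty")
    if n > coords.shape[0]:
        raise ValueError(f"cannot place {n} centers in {coords.shape[0]} voxels")
    if min_sep <= 0:
        picks = rng.choice(coords.shape[0], size=n, replace=False)
        return [coords[i].astype(float) for i in picks]
    order = rng.permutation(coords.shape[0])
    accepted: list[np.ndarray] = []
    min_sep_sq = min_sep**2
    for i in order:
        cand = coords[i].astype(float)
        if accepted:
            d2 = np.sum((np.asarray(accepted) - cand) ** 2, axis=1)
            if d2.min() < min_sep_sq:
                continue
        accepted.append(cand)
        if len(accepted) == n:
            return accepted
    raise ValueError(
        f"could not place {n} centers with min_sep={min_sep}; "
        f"only {len(accepted)} fit"
    )


def generate_phantom(
    spec: PhantomSpec, rng: Optional[np.random.Generator] = None
) -> Phantom:
    """Generate a synthetic cell.

    Deterministic given ``spec.seed`` (or an explicit generator).  The
    ground-truth masks are mutually consistent under priority fusion:
    the nucleus lies inside the cell, mitochondria inside the cytosol,
    and vesicles are non-overlapping spheres in the cytosol clear of the
    nucleus and mitochondria.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    lac = spec.lac_levels
    center = np.array(shape) / 2.0
    cell_axes = 0.44 * np.array(shape)
    cell = _ellipsoid(shape, center, cell_axes)

    nuc_axes = spec.nucleus_radius_frac * cell_axes
    nuc_center = center + np.array([0.0, 0.22 * cell_axes[1], 0.0])
    nucleus = _ellipsoid(shape, nuc_center, nuc_axes)
    nucleus &= cell
    cytosol = cell & ~nucleus

    log: list[dict] = []
    mito = np.zeros(shape, dtype=bool)
    if spec.n_mito > 0:
        # keep mitochondria clear of the membrane and nucleus
        interior = ndimage.distance_transform_edt(cytosol) > 5.0
        mito_centers = place_centers_uniform(
            spec.n_mito, interior, min_sep=10.0, rng=rng
        )
        for c in mito_centers:
            direction = rng.normal(size=3)
            long_axis = rng.uniform(8.0, 14.0)
            short_axis = rng.uniform(2.5, 3.5)
            mito |= _rotated_ellipsoid(shape, c, direction, long_axis, short_axis)
            log.append(
                {"kind": "mitochondria", "cx": c[0], "cy": c[1], "cz": c[2],
                 "size": long_axis}
            )
        mito &= cytosol

    vesicles = np.zeros(shape, dtype=np.int32)
    r_lo, r_hi = spec.vesicle_radius_range
    if spec.n_vesicles > 0:
        margin = r_hi + 1.0
        eligible = ndimage.distance_transform_edt(cytosol) > margin
        if mito.any():
            eligible &= ndimage.distance_transform_edt(~mito) > margin
        ves_centers = place_centers_uniform(
            spec.n_vesicles, eligible, min_sep=2.0 * r_hi + 2.0, rng=rng
        )
        for k, c in enumerate(ves_centers, start=1):
            r = rng.uniform(r_lo, r_hi)
            lo = np.maximum(np.floor(c - r), 0).astype(int)
            hi = np.minimum(np.ceil(c + r + 1), shape).astype(int)
            grids = np.meshgrid(
                *[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij"
            )
            dist = np.sqrt(sum((g - cc) ** 2 for g, cc in zip(grids, c)))
            inside = dist <= r
            vesicles[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][inside] = k
            log.append({"kind": "vesicle", "cx": c[0], "cy": c[1], "cz": c[2], "size": r})

    # LAC field: regions then dense-core gradient then Gaussian noise
    vol = np.full(shape, lac["outside"], dtype=np.float64)
    vol[cell] = lac["cytoplasm"]
    vol[nucleus] = lac["nucleus"]
    vol[mito] = lac["mitochondria"]
    if spec.n_vesicles > 0:
        for rec, k in zip([l for l in log if l["kind"] == "vesicle"],
                          range(1, int(vesicles.max()) + 1)):
            sel = vesicles == k
            c = np.array([rec["cx"], rec["cy"], rec["cz"]])
            r = rec["size"]
            idx = np.argwhere(sel)
            dist = np.linalg.norm(idx - c, axis=1)
            frac = np.clip(1.0 - dist / max(r, 1e-9), 0.0, 1.0)
            vol[tuple(idx.T)] = (
                lac["vesicle_rim"]
                + (lac["vesicle_core"] - lac["vesicle_rim"]) * frac
            )
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=shape)
    vol = np.clip(vol, 0.0, None)

    return Phantom(
        volume=Volume(vol.astype(np.float32)),
        gt_cell=BinaryMask(cell, class_name="cell"),
        gt_nucleus=BinaryMask(nucleus, class_name="nucleus"),
        gt_mito=BinaryMask(mito, class_name="mitochondria"),
        gt_vesicles=InstanceMap(vesicles),
        placement_log=log,
    )


def _corrupt(
    mask: np.ndarray,
    fn_rate: float,
    fp_rate: float,
    boundary_jitter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    out = mask.copy()
    if boundary_jitter > 0:
        if rng.random() < 0.5:
            out = ndimage.binary_dilation(out, iterations=boundary_jitter)
        else:
            out = ndimage.binary_erosion(out, iterations=boundary_jitter)
    if fn_rate > 0:
        drop = rng.random(out.shape) < fn_rate
        out &= ~(drop & out)
    if fp_rate > 0:
        speckle = rng.random(out.shape) < fp_rate
        out |= speckle & ~mask
    return out


def degrade_views(
    gt: BinaryMask,
    error: Union[tuple, Sequence[tuple]] = (0.1, 0.005, 0),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> ViewTriplet:
    """Simulate three independently corrupted single-view predictions.

    ``error`` is one ``(fn_rate, fp_rate, boundary_jitter)`` triple for
    all views or a sequence of three.  False negatives drop each true
    voxel independently with probability ``fn_rate``; false positives
    set background voxels with probability ``fp_rate``; jitter dilates
    or erodes the whole mask by the stated number of voxels (the
    direction chosen at random per view).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(error, tuple) and len(error) == 3 and np.isscalar(error[0]):
        errors = [error] * 3
    else:
        errors = list(error)
        if len(errors) != 3:
            raise ValueError("need one error triple or three")
    for fn_rate, fp_rate, jitter in errors:
        if not (0.0 <= fn_rate < 1.0 and 0.0 <= fp_rate < 1.0):
            raise ValueError("error rates must lie in [0, 1)")
    masks = [
        BinaryMask(_corrupt(gt.data, *err, rng=rng), class_name=gt.class_name)
        for err in errors
    ]
    return ViewTriplet(*masks)


def threshold_segment(
    vol: Volume,
    thresholds: Optional[dict] = None,
    smooth_sigma: float = 1.0,
    min_instance_voxels: int = 5,
) -> tuple[dict[str, BinaryMask], InstanceMap]:
    """Naive LAC-threshold segmentation backend.

    A Gaussian-smoothed copy of the volume is thresholded per class:
    cell above ``thresholds['cell']`` (largest component, holes filled),
    nucleus as the low-LAC interior below ``thresholds['nucleus']``,
    vesicles as connected components above ``thresholds['vesicle']``,
    and mitochondria in the band above ``thresholds['mitochondria']``
    clear of detected vesicles.  Intended for phantom pipelines, not for
    real tomograms.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    smoothed = ndimage.gaussian_filter(vol.data.astype(np.float64), smooth_sigma)

    cell_raw = smoothed > thr["cell"]
    if not cell_raw.any():
        raise ValueError("no voxels above the cell threshold")
    labeled, n = ndimage.label(cell_raw)
    largest = 1 + np.argmax(np.bincount(labeled.ravel())[1:])
    cell = ndimage.binary_fill_holes(labeled == largest)

    interior = ndimage.binary_erosion(cell, iterations=3)
    nuc_raw = interior & (smoothed < thr["nucleus"])
    if nuc_raw.any():
        labeled, n = ndimage.label(nuc_raw)
        largest = 1 + np.argmax(np.bincount(labeled.ravel())[1:])
        nucleus = ndimage.binary_fill_holes(labeled == largest)
    else:
        nucleus = np.zeros(vol.shape, dtype=bool)

    ves_raw = cell & ~nucleus & (smoothed > thr["vesicle"])
    labeled, n = ndimage.label(ves_raw)
    if n:
        counts = np.bincount(labeled.ravel())
        keep = np.flatnonzero(counts >= min_instance_voxels)
        keep = keep[keep > 0]
        lut = np.zeros(n + 1, dtype=np.int32)
        lut[keep] = np.arange(1, keep.size + 1)
        labeled = lut[labeled]
    vesicles = InstanceMap.from_labels(labeled)

    ves_zone = ndimage.binary_dilation(vesicles.data > 0, iterations=3)
    mito_raw = cell & ~nucleus & ~ves_zone & (smoothed > thr["mitochondria"])
    labeled, n = ndimage.label(mito_raw)
    mito = np.zeros(vol.shape, dtype=bool)
    if n:
        counts = np.bincount(labeled.ravel())
        for lab in range(1, n + 1):
            if counts[lab] >= min_instance_voxels:
                mito |= labeled == lab
    masks = {
        "cell": BinaryMask(cell, class_name="cell"),
        "nucleus": BinaryMask(nucleus, class_name="nucleus"),
        "mitochondria": BinaryMask(mito, class_name="mitochondria"),
    }
    return masks, vesicles
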