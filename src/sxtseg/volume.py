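"""Core containers and volume I/O for soft X-ray tomography data.

All 3D arrays follow the canonical ``(X, Y, Z)`` axis convention used
throughout the package: a tomogram of width 280, height 480 and depth 320
has shape ``(280, 480, 320)``.  Voxel indexing is 0-based.

Two on-disk formats are supported for grayscale volumes and label maps:

* multi-page **TIFF** (one page per X-slice), via :mod:`tifffile`;
* **MRC2014** single-volume maps, via a small built-in reader/writer
  (mode 2 float32 for intensity volumes, mode 1 int16 for label maps).

The five domain types mirror the stages of the pipeline: a raw ``Volume``
of linear absorption coefficient (LAC) values, per-class ``BinaryMask``
semantic masks, an ``InstanceMap`` of individually labeled insulin
vesicles, per-instance ``InstanceRecord`` summaries, and the final
``CellScene`` multi-organelle label field.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "Volume",
    "BinaryMask",
    "InstanceMap",
    "InstanceRecord",
    "CellScene",
    "SCENE_CODES",
    "read_volume",
    "write_volume",
    "read_label_volume",
    "write_label_volume",
    "extract_instances",
    "instances_to_table",
]

#: Categorical codes of the fused multi-organelle scene.
SCENE_CODES = {
    "outside": 0,
    "cytoplasm": 1,
    "mitochondria": 2,
    "nucleus": 3,
    "vesicle": 4,
}

SEMANTIC_CLASSES = ("cell", "nucleus", "mitochondria")


def _check_3d(data: np.ndarray, what: str) -> None:
    if data.ndim != 3:
        raise ValueError(f"{what} must be 3-dimensional, got ndim={data.ndim}")
    if min(data.shape) < 1:
        raise ValueError(f"{what} must have all shape components >= 1, got {data.shape}")


@dataclass
class Volume:
    """A 3D grid of linear absorption coefficient values.

    Parameters
    ----------
    data:
        3D float array, shape ``(nx, ny, nz)``.  Values are LAC in 1/µm
        (dimensionless if uncalibrated) and must be finite.
    voxel_size:
        Edge length of one voxel in µm.  LAC values are treated as given
        per voxel; no physical recalibration is applied.
    """

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        _check_3d(self.data, "Volume.data")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains NaN or Inf values")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A single-class 3D boolean mask (cell, nucleus or mitochondria)."""

    data: np.ndarray
    class_name: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_3d(self.data, "BinaryMask.data")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_count(self) -> int:
        return int(self.data.sum())


@dataclass
class InstanceMap:
    """A 3D integer label field: 0 is background, ``k > 0`` the k-th instance.

    Labels must form the contiguous set ``1..n_instances``; use
    :meth:`from_labels` to relabel an arbitrary non-negative label field
    on ingest.  Contiguity keeps instance identities stable for matching
    and for the radial distribution function.
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_3d(self.data, "InstanceMap.data")
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.array_equal(self.data, np.round(self.data)):
                raise ValueError("InstanceMap requires integer labels")
            self.data = self.data.astype(np.int32)
        if self.data.min() < 0:
            raise ValueError("InstanceMap labels must be non-negative")
        labels = np.unique(self.data)
        labels = labels[labels > 0]
        if labels.size and not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValueError(
                "InstanceMap labels must be contiguous 1..n; "
                "use InstanceMap.from_labels to relabel"
            )
        self.data = self.data.astype(np.int32)

    @classmethod
    def from_labels(cls, data: np.ndarray) -> "InstanceMap":
        """Build an InstanceMap from any non-negative label field, relabeling
        the positive labels to 1..n in ascending order of original label."""
        data = np.asarray(data)
        labels = np.unique(data)
        labels = labels[labels > 0]
        lut = np.zeros(int(data.max()) + 1 if data.size else 1, dtype=np.int32)
        lut[labels] = np.arange(1, labels.size + 1, dtype=np.int32)
        return cls(lut[data.astype(np.int64)])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_instances(self) -> int:
        return int(self.data.max())


@dataclass
class InstanceRecord:
    """Summary of one segmented instance.

    ``equiv_radius`` is the radius of the sphere with the instance's
    voxel volume, ``(3 V / 4π)^{1/3}``; instance matching operates on
    fused 3D instances, so radii are 3D throughout.
    """

    label: int
    voxel_count: int
    centroid: np.ndarray
    equiv_radius: float
    mean_lac: Optional[float] = None

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        if self.voxel_count < 1:
            raise ValueError("voxel_count must be >= 1")
        if self.equiv_radius <= 0:
            raise ValueError("equiv_radius must be positive")


@dataclass
class CellScene:
    """Fused multi-organelle categorical field with codes 0–4.

    Codes: 0 outside cell, 1 cytoplasm, 2 mitochondria, 3 nucleus,
    4 insulin vesicle (see :data:`SCENE_CODES`).
    """

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_3d(self.data, "CellScene.data")
        if self.data.min() < 0 or self.data.max() > 4:
            raise ValueError("CellScene codes must lie in 0..4")
        self.data = self.data.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def class_mask(self, name: str) -> np.ndarray:
        return self.data == SCENE_CODES[name]


# ---------------------------------------------------------------------------
# MRC2014 I/O (single 3D volume, modes 0/1/2/6)
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODE_OF = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _write_mrc(path: Path, data: np.ndarray, voxel_size: float) -> None:
    dtype = np.dtype(data.dtype)
    if dtype not in _MRC_MODE_OF:
        raise ValueError(f"unsupported dtype for MRC: {dtype}")
    mode = _MRC_MODE_OF[dtype]
    nx, ny, nz = data.shape
    header = bytearray(1024)
    struct.pack_into("<10i", header, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    struct.pack_into(
        "<6f", header, 40,
        nx * voxel_size, ny * voxel_size, nz * voxel_size, 90.0, 90.0, 90.0,
    )
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # column=X fastest
    stats = data.astype(np.float64)
    struct.pack_into("<3f", header, 76, float(stats.min()), float(stats.max()), float(stats.mean()))
    struct.pack_into("<2i", header, 88, 1, 0)  # ispg, nsymbt
    header[208:212] = b"MAP "
    header[212:216] = b"\x44\x44\x00\x00"  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(stats.std()))
    struct.pack_into("<i", header, 220, 0)  # nlabl
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        # MRC stores the first (column) axis fastest; transpose to (Z, Y, X)
        fh.write(np.ascontiguousarray(data.transpose(2, 1, 0)).tobytes())


def _read_mrc(path: Path) -> tuple[np.ndarray, float]:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise ValueError(f"{path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        if mode not in _MRC_MODES:
            raise ValueError(f"{path}: unsupported MRC mode {mode}")
        mapc, mapr, maps = struct.unpack_from("<3i", header, 64)
        if (mapc, mapr, maps) != (1, 2, 3):
            raise ValueError(f"{path}: unsupported MRC axis order {(mapc, mapr, maps)}")
        nsymbt = struct.unpack_from("<i", header, 92)[0]
        xlen = struct.unpack_from("<f", header, 40)[0]
        if nsymbt:
            fh.read(nsymbt)
        dtype = np.dtype(_MRC_MODES[mode])
        raw = fh.read(nx * ny * nz * dtype.itemsize)
    arr = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx).transpose(2, 1, 0)
    voxel_size = (xlen / nx) if (nx and xlen > 0) else 1.0
    return np.ascontiguousarray(arr), voxel_size


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format is not None:
        if format not in ("mrc", "tiff"):
            raise ValueError(f"unknown format {format!r}; expected 'mrc' or 'tiff'")
        return format
    suffix = path.suffix.lower()
    if suffix in (".mrc", ".map", ".rec"):
        return "mrc"
    if suffix in (".tif", ".tiff"):
        return "tiff"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_volume(path, format: Optional[str] = None) -> Volume:
    """Read a 3D grayscale volume from MRC or multi-page TIFF.

    TIFF pages are X-slices: a file of ``nx`` pages of shape
    ``(ny, nz)`` yields a Volume of shape ``(nx, ny, nz)``.
    Rejects non-3D data and non-finite values with explicit messages.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "mrc":
        data, voxel_size = _read_mrc(path)
    else:
        data = tifffile.imread(path)
        voxel_size = 1.0
    data = np.asarray(data)
    if data.ndim == 2:  # single-page TIFF
        raise ValueError(f"{path}: expected a 3D stack, got a single 2D image")
    _check_3d(data, str(path))
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains NaN or Inf values")
    return Volume(data.astype(np.float32), voxel_size=voxel_size)


def write_volume(vol: Volume, path, format: Optional[str] = None) -> None:
    """Write a Volume to MRC (mode 2, float32) or multi-page TIFF; the
    inverse of :func:`read_volume` at float32 precision."""
    path = Path(path)
    fmt = _infer_format(path, format)
    data = vol.data.astype(np.float32)
    if fmt == "mrc":
        _write_mrc(path, data, vol.voxel_size)
    else:
        tifffile.imwrite(path, data)


def read_label_volume(path, format: Optional[str] = None) -> np.ndarray:
    """Read an integer label volume (mask or instance map) losslessly."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    fmt = _infer_format(path, format)
    if fmt == "mrc":
        data, _ = _read_mrc(path)
    else:
        data = np.asarray(tifffile.imread(path))
    _check_3d(data, str(path))
    if not np.issubdtype(data.dtype, np.integer):
        if not np.array_equal(data, np.round(data)):
            raise ValueError(f"{path}: label volume has non-integer values")
        data = data.astype(np.int32)
    return data.astype(np.int32)


def write_label_volume(data: np.ndarray, path, format: Optional[str] = None) -> None:
    """Write a label volume as uint16 TIFF or MRC mode 1 (int16)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    data = np.asarray(data)
    if data.min() < 0:
        raise ValueError("label volumes must be non-negative")
    if fmt == "mrc":
        if data.max() > np.iinfo(np.int16).max:
            raise ValueError("label values exceed MRC mode-1 (int16) range")
        _write_mrc(path, data.astype(np.int16), 1.0)
    else:
        if data.max() > np.iinfo(np.uint16).max:
            raise ValueError("label values exceed uint16 TIFF range")
        tifffile.imwrite(path, data.astype(np.uint16))


# ---------------------------------------------------------------------------
# Instance summaries
# ---------------------------------------------------------------------------

def equivalent_radius(voxel_count: int) -> float:
    """Radius of the sphere whose volume equals ``voxel_count`` voxels."""
    return float((3.0 * voxel_count / (4.0 * np.pi)) ** (1.0 / 3.0))


def extract_instances(
    imap: InstanceMap, vol: Optional[Volume] = None
) -> list[InstanceRecord]:
    """Summarize each labeled instance: voxel count, centroid, equivalent
    radius, and (when a Volume is supplied) mean LAC.

    Returns an empty list for an empty map.
    """
    n = imap.n_instances
    if n == 0:
        return []
    if vol is not None and vol.shape != imap.shape:
        raise ValueError("Volume and InstanceMap shapes differ")
    labels = np.arange(1, n + 1)
    counts = np.bincount(imap.data.ravel(), minlength=n + 1)[1:]
    centroids = ndimage.center_of_mass(np.ones(imap.shape), imap.data, labels)
    means = (
        ndimage.mean(vol.data, imap.data, labels) if vol is not None else [None] * n
    )
    return [
        InstanceRecord(
            label=int(lab),
            voxel_count=int(cnt),
            centroid=np.asarray(cen, dtype=float),
            equiv_radius=equivalent_radius(int(cnt)),
            mean_lac=None if m is None else float(m),
        )
        for lab, cnt, cen, m in zip(labels, counts, centroids, means)
    ]


def instances_to_table(records: Sequence[InstanceRecord]) -> pd.DataFrame:
    """Tabulate instance records (columns: label, voxel_count, cx, cy, cz,
    equiv_radius, mean_lac) for CSV export."""
    return pd.DataFrame(
        {
            "label": [r.label for r in records],
            "voxel_count": [r.voxel_count for r in records],
            "cx": [r.centroid[0] for r in records],
            "cy": [r.centroid[1] for r in records],
            "cz": [r.centroid[2] for r in records],
            "equiv_radius": [r.equiv_radius for r in records],
            "mean_lac": [r.mean_lac for r in records],
        }
    )
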