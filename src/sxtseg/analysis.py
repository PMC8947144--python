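"""Mesoscale spatial statistics of the segmented cell.

The cytosol (cell minus nucleus) is partitioned into 8 concentric
shells by the normalized depth

    λ = d_nuc / (d_nuc + d_pm),

where d_nuc and d_pm are the Euclidean distances of a cytosol voxel to
the nucleus and to the plasma membrane.  Shell r1 hugs the nucleus,
shell r8 the plasma membrane; normalized depth removes cell-shape bias,
so shells have equal relative thickness in every direction.  Binning by
absolute distance to the nucleus is available as an alternative mode.

On that partition three radial distribution functions (RDFs) are
computed as density-in-shell over mean density,

    g_k = (count_k / shell_volume_k) / (N_total / cytosol_volume),

for three populations: insulin-vesicle instance centers, mitochondria
voxels, and vesicle–mitochondria contact centers.  g = 1 in every shell
is the uniform (random-placement) baseline; the volume-weighted mean of
g is identically 1.  A contact is a 26-connected region of vesicle
voxels lying within 1.5 voxels of the mitochondria surface.

Per-vesicle LAC profiles bin instance voxels by Euclidean distance to
the instance boundary; insulin vesicles are dense-core, so mean LAC
rises from the boundary bins to the center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .volume import BinaryMask, InstanceMap, Volume

__all__ = [
    "ShellPartition",
    "RDFProfile",
    "ContactSet",
    "LACProfile",
    "distance_fields",
    "shell_partition",
    "rdf_points",
    "rdf_voxels",
    "detect_contacts",
    "rdf_contacts",
    "lac_radial_profile",
    "functional_regions",
]

DEFAULT_N_SHELLS = 8
DEFAULT_CONTACT_CUTOFF = 1.5

#: 26-connectivity structuring element for contact components.
_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ShellPartition:
    """The concentric shell decomposition of the cytosol.

    ``shell_index`` is 0 outside the cytosol and 1..n_shells inside,
    with shell 1 nearest the nucleus and shell ``n_shells`` nearest the
    plasma membrane.  ``shell_volumes`` are voxel counts per shell and
    sum exactly to the cytosol volume.
    """

    shell_index: np.ndarray
    n_shells: int
    shell_volumes: np.ndarray
    mode: str = "relative"

    @property
    def cytosol_volume(self) -> int:
        return int(self.shell_volumes.sum())


@dataclass
class RDFProfile:
    """Per-shell normalized density g of one population.

    ``counts`` holds the raw per-shell totals (instance centers, voxels
    or contact centers); their sum is the population total inside the
    cytosol.  The shell-volume-weighted mean of ``g`` is 1 whenever the
    population is nonempty.
    """

    g: np.ndarray
    counts: np.ndarray
    population: str
    shell_volumes: np.ndarray

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shell": np.arange(1, len(self.g) + 1),
                "count": self.counts,
                "shell_volume": self.shell_volumes,
                "g": self.g,
            }
        )


@dataclass
class ContactSet:
    """Vesicle–mitochondria contact regions and their centroids."""

    contacts: InstanceMap
    centers: list[np.ndarray]

    @property
    def n_contacts(self) -> int:
        return self.contacts.n_instances


@dataclass
class LACProfile:
    """Mean LAC per 1-voxel-wide distance-to-boundary bin of one instance.

    Bin b collects instance voxels whose interior Euclidean distance to
    the boundary lies in [b, b+1); bin 1 is the outermost layer.
    ``center_voxel`` is the instance voxel of maximal LAC.
    """

    boundary_distance_bins: np.ndarray
    mean_lac: np.ndarray
    bin_counts: np.ndarray
    center_voxel: np.ndarray


def distance_fields(
    cell: BinaryMask, nucleus: BinaryMask
) -> tuple[np.ndarray, np.ndarray]:
    """Euclidean distance of every voxel to the nucleus and to the
    plasma membrane.

    ``d_nuc`` is the distance to the nearest nucleus voxel, ``d_pm`` the
    distance to the nearest non-cell voxel; both are meaningful on
    cytosol voxels.  A nucleus reaching outside the cell triggers a
    warning and the computation proceeds on the intersection.
    """
    if not cell.data.any():
        raise ValueError("cell mask is empty")
    if not nucleus.data.any():
        raise ValueError("nucleus mask is empty")
    nuc = nucleus.data
    if (nuc & ~cell.data).any():
        warnings.warn(
            "nucleus mask extends outside the cell mask; using the intersection",
            stacklevel=2,
        )
        nuc = nuc & cell.data
        if not nuc.any():
            raise ValueError("nucleus mask does not intersect the cell mask")
    d_nuc = ndimage.distance_transform_edt(~nuc)
    d_pm = ndimage.distance_transform_edt(cell.data)
    return d_nuc, d_pm


def shell_partition(
    d_nuc: np.ndarray,
    d_pm: np.ndarray,
    n_shells: int = DEFAULT_N_SHELLS,
    mode: str = "relative",
    cytosol: Optional[np.ndarray] = None,
) -> ShellPartition:
    """Partition the cytosol into concentric shells.

    ``mode='relative'`` (default) bins the normalized depth
    λ = d_nuc/(d_nuc+d_pm) into n_shells equal intervals, with shell k
    covering λ in [(k-1)/n, k/n) and λ = 1 assigned to the last shell.
    ``mode='absolute'`` bins d_nuc into n_shells equal-width intervals
    up to its cytosol maximum.  The cytosol is recovered from the
    distance fields themselves (inside the cell, outside the nucleus)
    unless a mask is given explicitly.
    """
    if cytosol is None:
        cytosol = (d_nuc > 0) & (d_pm > 0)
    cytosol = np.asarray(cytosol).astype(bool)
    if n_shells < 1:
        raise ValueError("n_shells must be >= 1")
    if mode not in ("relative", "absolute"):
        raise ValueError(f"unknown shell mode {mode!r}")
    if not cytosol.any():
        raise ValueError("cytosol mask is empty")
    total = d_nuc + d_pm
    if np.any(total[cytosol] == 0):
        raise ValueError("cytosol voxel with zero nucleus+membrane distance")
    shell = np.zeros(cytosol.shape, dtype=np.int32)
    if mode == "relative":
        lam = np.zeros_like(total)
        np.divide(d_nuc, total, out=lam, where=total > 0)
        idx = np.minimum((lam[cytosol] * n_shells).astype(np.int32), n_shells - 1)
    else:
        dmax = d_nuc[cytosol].max()
        idx = np.minimum(
            (d_nuc[cytosol] / dmax * n_shells).astype(np.int32), n_shells - 1
        )
    shell[cytosol] = idx + 1
    volumes = np.bincount(shell[cytosol], minlength=n_shells + 1)[1:]
    return ShellPartition(
        shell_index=shell, n_shells=n_shells, shell_volumes=volumes, mode=mode
    )


def _g_from_counts(counts: np.ndarray, shells: ShellPartition) -> np.ndarray:
    total = counts.sum()
    if total == 0:
        raise ValueError("population is empty inside the cytosol")
    mean_density = total / shells.cytosol_volume
    with np.errstate(divide="ignore", invalid="ignore"):
        g = (counts / shells.shell_volumes) / mean_density
    return np.where(shells.shell_volumes > 0, g, 0.0)


def rdf_points(
    centers: Sequence[np.ndarray],
    shells: ShellPartition,
    population: str = "vesicle_number",
) -> RDFProfile:
    """RDF of a point population (e.g. vesicle instance centers).

    Each center is assigned to the shell of its nearest voxel; centers
    outside the cytosol (in the nucleus or beyond the membrane) are
    discarded with a warning.
    """
    if len(centers) == 0:
        raise ValueError("rdf_points requires at least one center")
    coords = np.rint(np.asarray(centers, dtype=float)).astype(int)
    shape = shells.shell_index.shape
    coords = np.clip(coords, 0, np.array(shape) - 1)
    shell_ids = shells.shell_index[tuple(coords.T)]
    n_discarded = int(np.count_nonzero(shell_ids == 0))
    if n_discarded:
        warnings.warn(
            f"{n_discarded} center(s) outside the cytosol discarded", stacklevel=2
        )
    counts = np.bincount(
        shell_ids[shell_ids > 0], minlength=shells.n_shells + 1
    )[1:]
    return RDFProfile(
        g=_g_from_counts(counts, shells),
        counts=counts,
        population=population,
        shell_volumes=shells.shell_volumes.copy(),
    )


def rdf_voxels(mask: BinaryMask, shells: ShellPartition) -> RDFProfile:
    """RDF of a voxel population (mitochondria): per-shell voxel tallies
    normalized by shell volume over mean density."""
    if not mask.data.any():
        raise ValueError("rdf_voxels requires a nonempty mask")
    shell_ids = shells.shell_index[mask.data]
    counts = np.bincount(shell_ids[shell_ids > 0], minlength=shells.n_shells + 1)[1:]
    return RDFProfile(
        g=_g_from_counts(counts, shells),
        counts=counts,
        population="mitochondria_voxel",
        shell_volumes=shells.shell_volumes.copy(),
    )


def detect_contacts(
    vesicles: InstanceMap,
    mito: BinaryMask,
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> ContactSet:
    """Find vesicle–mitochondria contact sites.

    Contact voxels are vesicle voxels whose Euclidean distance to the
    nearest mitochondria voxel is strictly below ``cutoff`` (1.5 voxels
    by default; a mitochondria voxel itself is at distance 0).  Contacts
    are the 26-connected components of the contact voxels; centers are
    component centroids.  An empty result is not an error.
    """
    if vesicles.shape != mito.shape:
        raise ValueError("vesicle and mitochondria shapes differ")
    if mito.data.any():
        d_mito = ndimage.distance_transform_edt(~mito.data)
        contact_vox = (vesicles.data > 0) & (d_mito < cutoff)
    else:
        contact_vox = np.zeros(vesicles.shape, dtype=bool)
    labeled, n = ndimage.label(contact_vox, structure=_CONN26)
    centers = [
        np.asarray(c, dtype=float)
        for c in ndimage.center_of_mass(contact_vox, labeled, range(1, n + 1))
    ]
    return ContactSet(contacts=InstanceMap.from_labels(labeled), centers=centers)


def rdf_contacts(contacts: ContactSet, shells: ShellPartition) -> RDFProfile:
    """RDF of contact centers; g is undefined (raises) for an empty
    contact set."""
    if not contacts.centers:
        raise ValueError("contact set is empty; RDF undefined")
    return rdf_points(contacts.centers, shells, population="contact")


def lac_radial_profile(vol: Volume, instance: np.ndarray) -> LACProfile:
    """Radial LAC profile of one instance.

    The interior Euclidean distance to the instance boundary is computed
    per voxel and binned at 1-voxel width ([1, 2) is the outermost bin);
    the per-bin mean LAC and the max-LAC center voxel (first in scan
    order on ties) are reported.  Bin counts sum to the instance voxel
    count.
    """
    instance = np.asarray(instance).astype(bool)
    if instance.shape != vol.shape:
        raise ValueError("instance mask must match the volume shape")
    if not instance.any():
        raise ValueError("instance is empty")
    depth = ndimage.distance_transform_edt(instance)
    bins = np.floor(depth[instance]).astype(int)  # >= 1 for instance voxels
    values = vol.data[instance]
    max_bin = bins.max()
    counts = np.bincount(bins, minlength=max_bin + 1)[1:]
    sums = np.bincount(bins, weights=values, minlength=max_bin + 1)[1:]
    keep = counts > 0
    with np.errstate(invalid="ignore"):
        means = np.where(keep, sums / np.maximum(counts, 1), np.nan)
    masked = np.where(instance, vol.data, -np.inf)
    center = np.unravel_index(int(np.argmax(masked)), vol.shape)
    return LACProfile(
        boundary_distance_bins=np.arange(1, max_bin + 1),
        mean_lac=means,
        bin_counts=counts,
        center_voxel=np.asarray(center),
    )


_REGIONS = {1: "perinuclear", 2: "maturation", 3: "maturation"}
_REGIONS.update({k: "transportation" for k in (4, 5, 6)})
_REGIONS.update({k: "secretion" for k in (7, 8)})


def functional_regions(shell_id: int) -> str:
    """Functional annotation of the 8 cytosol shells: r1 perinuclear,
    r2–r3 vesicle maturation, r4–r6 transportation, r7–r8 secretion."""
    if shell_id not in _REGIONS:
        raise ValueError(f"shell_id must lie in 1..8, got {shell_id}")
    return _REGIONS[shell_id]
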