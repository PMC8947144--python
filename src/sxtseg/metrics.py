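"""Segmentation evaluation metrics and contrast diagnostics.

Semantic masks are scored with the Dice coefficient,

    dice = 2 |P ∩ G| / (|P| + |G|),

instance segmentations with a center-distance Recall and with AP50.
A predicted and a ground-truth instance match for Recall when the
normalized center distance

    d = d_u / (r_pred + r_gt)

is below 1, where d_u is the Euclidean centroid distance and the radii
are equivalent-sphere radii of the two instances.  AP50 is standard
single-class average precision with a 3D mask-IoU threshold of 0.5.

The contrast-ratio diagnostics quantify how distinct an organelle is
from its cytoplasmic surround on per-slice max-normalized intensity;
mitochondria sit near 1.1, which is why their masks are the hardest to
segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import ndimage

from .fusion import iou as _mask_iou
from .volume import BinaryMask, InstanceMap, InstanceRecord, Volume

__all__ = [
    "MatchResult",
    "MetricsReport",
    "dice",
    "match_distance",
    "instance_recall",
    "average_precision_50",
    "normalized_intensity",
    "contrast_ratio",
]

ArrayLike = Union[np.ndarray, BinaryMask]


def _as_bool(mask: ArrayLike) -> np.ndarray:
    if isinstance(mask, BinaryMask):
        return mask.data
    return np.asarray(mask).astype(bool)


@dataclass
class MatchResult:
    """Outcome of instance matching: matched (pred, gt, d) triples and
    the derived true-positive / false-negative / false-positive counts."""

    pairs: list[tuple[int, int, float]]
    tp: int
    fn: int
    fp: int


@dataclass
class MetricsReport:
    """Bundle of evaluation numbers for one predicted/ground-truth scene
    pair, mirroring the JSON report written by the CLI."""

    dice_per_class: dict[str, float]
    recall: float
    ap50: float
    n_instances_pred: int
    n_instances_gt: int

    def to_dict(self) -> dict:
        return {
            "dice_per_class": self.dice_per_class,
            "recall": self.recall,
            "ap50": self.ap50,
            "n_instances_pred": self.n_instances_pred,
            "n_instances_gt": self.n_instances_gt,
        }


def dice(pred: ArrayLike, gt: ArrayLike) -> float:
    """Dice coefficient 2|P∩G| / (|P|+|G|); symmetric, in [0, 1].

    Undefined (raises) when both masks are empty.  Related to IoU by
    dice = 2·IoU / (1 + IoU).
    """
    p, g = _as_bool(pred), _as_bool(gt)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    denom = np.count_nonzero(p) + np.count_nonzero(g)
    if denom == 0:
        raise ValueError("Dice is undefined for two empty masks")
    return 2.0 * np.count_nonzero(p & g) / denom


def match_distance(pred: InstanceRecord, gt: InstanceRecord) -> float:
    """Normalized center distance d = d_u / (r_pred + r_gt); a pair with
    d < 1 counts as a true positive."""
    d_u = float(np.linalg.norm(pred.centroid - gt.centroid))
    return d_u / (pred.equiv_radius + gt.equiv_radius)


def instance_recall(
    pred: Sequence[InstanceRecord], gt: Sequence[InstanceRecord]
) -> tuple[float, MatchResult]:
    """Center-distance instance recall.

    All (pred, gt) pairs with d < 1 are matched greedily in ascending d,
    one-to-one; matched ground-truth instances are true positives and
    recall = T_p / (T_p + F_n).  Deterministic and exact for
    well-separated instances.
    """
    if not gt:
        raise ValueError("instance_recall requires a nonempty ground truth")
    cands = [
        (match_distance(p, g), pi, gi)
        for pi, p in enumerate(pred)
        for gi, g in enumerate(gt)
    ]
    cands = [c for c in cands if c[0] < 1.0]
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    used_p: set[int] = set()
    used_g: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, pi, gi in cands:
        if pi in used_p or gi in used_g:
            continue
        used_p.add(pi)
        used_g.add(gi)
        pairs.append((pred[pi].label, gt[gi].label, d))
    tp = len(pairs)
    result = MatchResult(pairs=pairs, tp=tp, fn=len(gt) - tp, fp=len(pred) - tp)
    return tp / len(gt), result


def _instance_iou_table(pred: InstanceMap, gt: InstanceMap) -> np.ndarray:
    """Dense (n_pred+1, n_gt+1) IoU table from the joint label histogram."""
    p, g = pred.data.ravel(), gt.data.ravel()
    np_, ng = pred.n_instances, gt.n_instances
    joint = np.zeros((np_ + 1, ng + 1), dtype=np.int64)
    np.add.at(joint, (p, g), 1)
    p_areas = joint.sum(axis=1)
    g_areas = joint.sum(axis=0)
    union = p_areas[:, None] + g_areas[None, :] - joint
    with np.errstate(divide="ignore", invalid="ignore"):
        table = np.where(union > 0, joint / union, 0.0)
    table[0, :] = 0.0
    table[:, 0] = 0.0
    return table


def average_precision_50(
    pred: InstanceMap,
    gt: InstanceMap,
    scores: Optional[Sequence[float]] = None,
    iou_threshold: float = 0.5,
) -> float:
    """Single-class average precision at 3D mask IoU >= ``iou_threshold``.

    Predictions are processed in descending confidence (uniform scores
    allowed; ties broken by label) and matched one-to-one to the
    unclaimed ground-truth instance of highest IoU.  The AP integral
    uses the all-point interpolated precision envelope.
    """
    if gt.n_instances == 0:
        raise ValueError("AP50 requires a nonempty ground truth")
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    n_pred = pred.n_instances
    if n_pred == 0:
        return 0.0
    if scores is None:
        scores = np.ones(n_pred)
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (n_pred,):
        raise ValueError(f"need one score per prediction ({n_pred}), got {scores.shape}")
    table = _instance_iou_table(pred, gt)
    order = sorted(range(1, n_pred + 1), key=lambda lab: (-scores[lab - 1], lab))
    claimed: set[int] = set()
    tp_flags = []
    for lab in order:
        ious = table[lab]
        best_g, best_iou = 0, 0.0
        for g in range(1, gt.n_instances + 1):
            if g not in claimed and ious[g] > best_iou:
                best_g, best_iou = g, ious[g]
        if best_g and best_iou >= iou_threshold:
            claimed.add(best_g)
            tp_flags.append(True)
        else:
            tp_flags.append(False)
    tp_cum = np.cumsum(tp_flags)
    precision = tp_cum / np.arange(1, n_pred + 1)
    recall = tp_cum / gt.n_instances
    # all-point interpolation: precision envelope, integrate over recall steps
    env = np.maximum.accumulate(precision[::-1])[::-1]
    ap = 0.0
    prev_r = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def normalized_intensity(slice2d: np.ndarray) -> np.ndarray:
    """Normalize a 2D orthoslice by its maximum intensity, mapping the
    slice into [0, 1] with maximum exactly 1."""
    slice2d = np.asarray(slice2d, dtype=float)
    peak = slice2d.max()
    if peak <= 0:
        raise ValueError("normalized_intensity requires a positive slice maximum")
    return slice2d / peak


def contrast_ratio(
    vol: Volume,
    organelle: ArrayLike,
    context: ArrayLike,
    shell_width: int = 2,
    exclude: Sequence[ArrayLike] = (),
) -> float:
    """Mean normalized intensity of an organelle over its cytoplasmic
    surround.

    The surround is the morphological dilation of the organelle by
    ``shell_width`` voxels, restricted to ``context`` (typically the
    cell mask), minus the organelle itself and any masks in ``exclude``
    (other organelles).  Intensities are max-normalized per X-slice and
    the organelle/surround ratio is averaged over slices containing both.
    """
    org = _as_bool(organelle)
    ctx = _as_bool(context)
    if org.shape != vol.shape or ctx.shape != vol.shape:
        raise ValueError("mask shapes must match the volume")
    if not org.any():
        raise ValueError("organelle mask is empty")
    if shell_width < 1:
        raise ValueError("shell_width must be >= 1")
    shell = ndimage.binary_dilation(org, iterations=shell_width) & ctx & ~org
    for other in exclude:
        shell &= ~_as_bool(other)
    if not shell.any():
        raise ValueError("surrounding shell is empty")
    ratios = []
    for x in range(vol.shape[0]):
        o, s = org[x], shell[x]
        if not (o.any() and s.any()):
            continue
        norm = normalized_intensity(vol.data[x])
        mean_shell = norm[s].mean()
        if mean_shell > 0:
            ratios.append(norm[o].mean() / mean_shell)
    if not ratios:
        raise ValueError("no slice contains both organelle and surround")
    return float(np.mean(ratios))
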