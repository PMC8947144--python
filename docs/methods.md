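# Methods

This note documents the models and procedures implemented in `sxtseg`,
the choices made where the design was genuinely open, and what the
synthetic phantoms do and do not establish about real tomograms.

## Conventions

All volumes use the axis order (X, Y, Z) with 0-based voxel indexing;
the canonical preprocessed tomogram grid is (280, 480, 320). LAC values
are treated as given per voxel — no physical voxel size is required for
any statistic in the package, so `voxel_size` is metadata only. Volumes
are stored as float32 (MRC mode 2 or multi-page TIFF, one page per
X-slice); label maps as int16/uint16. The MRC reader/writer is a
minimal MRC2014 implementation restricted to single-volume maps with
standard axis order; round-trips are bit-exact and the byte layout is
cross-checked in the test suite against an independent CCP4/MRC parser.

## Fusion

**Multi-view voting.** Each semantic class has three single-view 3D
masks, one per slicing axis. The fused voxel is foreground iff at least
two views agree. Under independent per-voxel view errors of rate p the
fused error rate is p²(3−2p) < p, which is why fusion reliably improves
Dice; the acceptance suite verifies the improvement empirically on
seeded degradations.

**Instance linking.** 2D vesicle instances on adjacent slices join when
the IoU of their full 2D footprints (not bounding boxes) is *strictly*
greater than 0.5. Open choices resolved here:

- One-to-one chaining: when an instance exceeds the threshold against
  several candidates on the next slice it links only to the highest-IoU
  one (ties to the lower label). This prevents uncontrolled merging of
  neighboring vesicles and makes the result order-independent.
- No gap bridging: an instance missing from one slice terminates its
  chain. Vesicles are small; bridging would invent continuity the
  predictions do not support.
- Linking runs along one axis (the instance-prediction axis); 3-view
  fusion applies to semantic masks only.

Note that a full sphere does **not** satisfy the linking precondition
at its polar caps — adjacent cross-sections there shrink too fast to
keep IoU above 0.5 — so exact-count recovery is guaranteed (and tested)
for solids whose adjacent cross-sections all exceed the threshold,
e.g. equatorial bands of spheres.

**Priority merge.** Scene codes are 0 outside, 1 cytoplasm,
2 mitochondria, 3 nucleus, 4 vesicle, assigned in increasing priority
cell < mitochondria < nucleus < vesicle. The rule is applied literally:
an organelle voxel outside the cell mask keeps its organelle code, and
`priority_qc` reports such voxels as a consistency diagnostic rather
than silently clipping them.

## Evaluation metrics

- Dice on binary masks; undefined (an error) when both masks are empty.
- Instance Recall: the normalized center distance
  d = d_u / (r_pred + r_gt) uses 3D equivalent-sphere radii
  (3V/4π)^{1/3}, since matching operates on fused 3D instances. Pairs
  with d < 1 are matched greedily in ascending d, one-to-one — exact
  for well-separated instances (verified against exhaustive assignment
  on small scenes) and deterministic everywhere.
- AP50: standard single-class average precision, predictions in
  descending confidence, match criterion 3D mask IoU ≥ 0.5, one-to-one,
  all-point interpolated precision envelope. Uniform scores are allowed
  (ties broken by label), since thresholded backends have no
  confidence.
- Contrast ratio: organelle mean over surround mean of per-X-slice
  max-normalized intensity, averaged over slices containing both. The
  surround is a dilation shell (default width 2 voxels) inside the
  cell, minus the organelle and any excluded co-organelles. The shell
  width is a free parameter: real studies never pin down "surrounding
  pixels", so it is exposed as a knob with a conservative default.

## Shell partition and RDFs

The cytosol is every cell voxel outside the nucleus. Its 8-shell
partition uses the normalized depth λ = d_nuc/(d_nuc+d_pm) with both
distances Euclidean (exact EDTs); shell k covers λ ∈ [(k−1)/8, k/8),
λ = 1 falling into shell 8. Normalized depth — rather than absolute
distance — makes the shells cover the cytosol with equal *relative*
thickness in every direction, removing cell-shape bias; absolute-
distance binning is provided as `mode="absolute"` and results carry
their mode tag.

The RDF replaces the spherical 4πr²·dr normalization with empirical
shell volumes:

    g_k = (count_k / V_k) / (N_total / V_cytosol),

which is exact for arbitrary cell shapes and reduces to the spherical
form in the concentric-sphere limit. By construction the shell-volume-
weighted mean of g is identically 1, and uniform random placement gives
g ≈ 1 per shell (binomial fluctuations only) — both are tested.

Populations: vesicle RDFs count instance centers (geometric centroids;
the max-LAC "dense-core center" is computed separately for LAC
profiles, as the two differ in principle), mitochondria RDFs count
voxels, contact RDFs count contact-component centroids. Contacts are
26-connected components of vesicle voxels with EDT-to-mitochondria
< 1.5 voxels; connectivity is a choice (the criterion does not fix it)
and 26-connectivity avoids splitting one physical contact patch into
diagonal fragments.

Centers falling in the nucleus are discarded with a warning rather than
an error: upstream segmentations do occasionally place a vesicle
centroid inside the nuclear mask and the analysis should degrade
gracefully.

## LAC radial profiles

Per instance, the interior EDT to the boundary is binned at 1-voxel
width ([1, 2) is the outermost bin) and the mean LAC per bin is
reported; bin counts always sum to the instance volume. The instance
"center" here is the max-LAC voxel (first in scan order on ties).

## Synthetic phantoms

The generator emulates an INS-1E-like β-cell on a (140, 240, 160) grid
(half the canonical tomogram in each dimension — preserves geometry
while keeping whole-phantom analyses in seconds):

| region | mean LAC | rationale |
| --- | --- | --- |
| background | 0.10 | capillary medium |
| cytoplasm | 0.30 | reference level |
| nucleus | 0.25 | less dense than cytosol in SXT |
| mitochondria | 0.33 | contrast ratio 0.33/0.30 = 1.1, the low-contrast regime of real data |
| vesicle rim → core | 0.35 → 0.55 | dense-core gradient inside the 0.3–0.6 vesicle range |

Gaussian voxel noise (σ = 0.01) is added and the field clipped at 0.
Defaults: 20 tubular mitochondria (randomly oriented elongated
ellipsoids, long axis 8–14 voxels), 150 vesicles with radii 3–6 voxels.
Vesicles are placed uniformly over the cytosol *eroded by the maximum
vesicle radius* and clear of mitochondria, with pairwise separation
preventing overlap — so ground-truth masks are mutually disjoint and
survive the priority merge unchanged. Two consequences worth knowing:

- vesicle centers cannot reach the innermost/outermost shells, so the
  *phantom-truth* vesicle RDF is mid-cytosol-enriched by construction
  (uniform-RDF tests therefore place bare centers, not vesicles);
- phantom ground truth contains no vesicle–mitochondria contacts;
  contact statistics are tested on purpose-built touching scenes.

All randomness flows through one seeded `numpy` Generator passed
explicitly; identical seeds give bit-identical phantoms. With organelle
counts set to zero the phantom geometry (cell + nucleus) is fully
deterministic.

The degradation simulator corrupts a mask per view with boundary jitter
(whole-mask dilation or erosion), then independent voxel drop-out
(false-negative rate), then background speckle (false-positive rate) —
a deliberately simple error model: it captures rate-level behavior and
view independence, not the spatially correlated failure modes of real
networks. The threshold backend (Gaussian smoothing + per-class LAC
cutoffs + connected components) exists to close the pipeline end-to-end
on phantoms; it is not a segmentation method for real tomograms.

Consequently, passing tests establish the *correctness of the
post-processing and statistics* under controlled conditions — voting
arithmetic, linking topology, metric identities, RDF normalization —
not the accuracy of any particular segmentation network on real SXT
data, which depends on tomogram quality and training.

## Numerical choices

- Patch tiling stride = ⌊extent·(1−overlap)⌋ with the last patch
  snapped to the border; "about 30 %" overlap is treated as a minimum.
  Border patches are clipped, never padded. Score ties in patch merging
  go to the earlier patch (determinism).
- Resizing: trilinear for intensities, nearest-neighbor for labels (no
  new labels introduced); resizing to the current shape is an exact
  no-op.
- IoU/linking threshold comparisons are strict (> 0.5); IoU and Dice of
  two empty masks raise rather than returning a conventional value.
- Instance labels are relabeled to contiguous 1..n on ingest.
- EDTs use exact Euclidean distance transforms; λ-binning uses
  half-open intervals with λ = 1 folded into the last shell.

## Problem sizes

Tests run phantoms at (70, 120, 80) and smaller; the acceptance
baseline uses the full default (140, 240, 160) geometry with 20 × 1,000
uniformly placed centers. Since the zero-organelle phantom geometry is
seed-independent, the shell partition is computed once and the 20
seeded placements are averaged — mathematically identical to
regenerating the phantom per seed.

## Known limitations

- No SXT projection physics: no missing-wedge artifacts, no capillary
  geometry, no reconstruction noise correlation.
- No capillary-line detection; crop boxes are user-supplied.
- Instance linking cannot bridge a slice-long gap in a chain.
- The threshold backend assumes the phantom's LAC ordering and fails on
  contrast regimes it was not designed for.
- Absolute-distance shell mode and relative-depth mode give different
  partitions for non-spherical cells; results are not comparable across
  modes.
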