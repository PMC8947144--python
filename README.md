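# sxtseg

Post-processing, fusion and mesoscale spatial analysis for organelle
segmentations of soft X-ray tomograms (SXT).

SXT images whole cells near-natively at ~25 nm resolution; each voxel
carries a linear absorption coefficient (LAC) proportional to local
molecular density. Automated pipelines segment such tomograms slice by
slice in 2D — semantic networks for cell / nucleus / mitochondria,
instance networks for individual insulin vesicles — and the scientific
questions (where do vesicles sit relative to the nucleus, how do
mitochondria redistribute under stimulation, where do vesicles touch
mitochondria) live entirely in the 3D post-processing. `sxtseg`
implements that post-processing and analysis stack:

- **Multi-view semantic fusion** — single-view 3D masks `V^X, V^Y, V^Z`
  reconstructed from per-axis 2D predictions are combined by per-voxel
  majority vote: `v_i = 1` iff `v_i^X + v_i^Y + v_i^Z ≥ 2`.
- **2D → 3D instance linking** — vesicle instances on adjacent slices
  are chained into one 3D instance when their footprint IoU exceeds
  0.5, transitively along the slicing axis.
- **Priority merging** — the per-class masks are flattened into one
  cell scene under `vesicle > nucleus > mitochondria > cell`.
- **Evaluation** — Dice = 2|P∩G| / (|P|+|G|); instance Recall with the
  normalized center distance d = d_u / (r_P + r_G) (a match iff d < 1,
  radii = equivalent-sphere radii); AP50 at 3D mask IoU ≥ 0.5;
  organelle/cytoplasm contrast ratios on per-slice max-normalized
  intensity.
- **Mesoscale statistics** — the cytosol is split into 8 concentric
  shells by normalized nucleus-to-membrane depth λ = d_nuc/(d_nuc+d_pm)
  (r1 perinuclear … r8 submembrane), and radial distribution functions
  g_k = (count_k / V_k) / (N / V_cytosol) are computed for vesicle
  centers, mitochondria voxels and vesicle–mitochondria contact centers
  (contact = vesicle voxels within 1.5 voxels of the mitochondria
  surface, 26-connected). g = 1 everywhere is the uniform baseline.
  Per-vesicle LAC profiles binned by distance to the instance boundary
  expose the dense-core signature (LAC rising toward the center).
- **Synthetic phantoms** — because SXT tomograms of INS-1E β-cells are
  not publicly deposited, a phantom generator emulates one: an
  ellipsoidal cell with an off-center nucleus, low-contrast
  mitochondria (~1.1 over cytosol), and dense-core vesicles with LAC in
  the 0.3–0.6 range, plus a prediction-degradation simulator and a
  naive threshold segmentation backend for end-to-end runs.

## Worked example

```python
import numpy as np
import sxtseg as sx

spec = sx.PhantomSpec(shape=(70, 120, 80), n_mito=6, n_vesicles=20, seed=1)
phantom = sx.generate_phantom(spec)

masks, vesicles = sx.threshold_segment(phantom.volume)
print("cell Dice        :", round(sx.dice(masks["cell"], phantom.gt_cell), 4))
print("nucleus Dice     :", round(sx.dice(masks["nucleus"], phantom.gt_nucleus), 4))
print("vesicles found   :", vesicles.n_instances, "of", phantom.gt_vesicles.n_instances)

recall, _ = sx.instance_recall(sx.extract_instances(vesicles),
                               sx.extract_instances(phantom.gt_vesicles))
print("instance recall  :", round(recall, 4))

d_nuc, d_pm = sx.distance_fields(phantom.gt_cell, phantom.gt_nucleus)
shells = sx.shell_partition(d_nuc, d_pm)
records = sx.extract_instances(phantom.gt_vesicles)
profile = sx.rdf_points([r.centroid for r in records], shells)
print("vesicle RDF g    :", np.round(profile.g, 2))

ratio = sx.contrast_ratio(phantom.volume, phantom.gt_mito, phantom.gt_cell,
                          exclude=[phantom.gt_nucleus,
                                   sx.BinaryMask(phantom.gt_vesicles.data > 0)])
print("mito contrast    :", round(ratio, 3))
```

prints

```
cell Dice        : 0.9896
nucleus Dice     : 0.9961
vesicles found   : 20 of 20
instance recall  : 1.0
vesicle RDF g    : [0.   0.   0.6  3.37 3.74 0.61 0.   0.  ]
mito contrast    : 1.099
```

The threshold backend recovers the phantom's cell and nucleus almost
perfectly (Dice ≈ 0.99) and every one of the 20 vesicles (Recall 1.0).
The vesicle RDF concentrates in mid-cytosol shells r3–r6: the generator
keeps vesicles a safety margin away from the nucleus and the plasma
membrane, so their centers cannot reach shells r1–r2 and r7–r8 — an
enrichment a uniform population (g = 1) would not show. The measured
mitochondria/cytosol contrast ratio 1.099 matches the generation target
0.33/0.30 = 1.1, the low contrast that makes mitochondria the hardest
class for any segmenter.

The same pipeline is scriptable from the shell — see `sxtseg --help`
(`simulate phantom`, `fuse semantic|instances|merge`, `evaluate`,
`analyze rdf|lac`).

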