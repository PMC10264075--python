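# osteomorph

High-density 3D geometric morphometrics of limb bones, built to answer one
question rigorously: **does a single-species bone sample contain two shape
morphs that are not explained by size?** The motivating use case is detecting
sexual dimorphism in fossil populations — for example a herd of coeval
ornithomimosaur dinosaurs known from dozens of femora and tibiae — where the
signal is a subtle, size-independent bimodality in shaft curvature and distal
epiphysis width.

The package implements the full analysis chain used in modern high-density
morphometrics, plus a synthetic bone-population generator that stands in for
fossil surface scans so that every statistical property of the pipeline can be
tested end to end.

## What it computes

1. **Landmarks and semilandmarks.** Configurations combine fixed anatomical
   landmarks with sliding semilandmarks on curves and surfaces (complete femur:
   25 + 99 + 495 = 619 points; complete tibia: 725; femoral epiphysis
   fragments: 479). Surface semilandmarks digitised once on a template
   specimen are transferred to every other specimen by thin-plate-spline (TPS)
   warping and snapped to the specimen mesh.
2. **Sliding relaxation.** Semilandmarks slide along their local tangent
   (curves) or tangent plane (surfaces) to minimise the bending energy of the
   TPS relating reference to specimen — the generalized-least-squares
   formulation. The protocol is 5 iterations against the template, then a
   partial Procrustes consensus is computed and 2 more iterations run against
   it.
3. **Partial generalized Procrustes analysis.** Configurations are centred,
   fixed at unit centroid size (CS), and iteratively rotated to the consensus;
   size survives only as log CS.
4. **PCA + per-axis Gaussian mixture models.** Each retained PC axis is fitted
   with univariate Gaussian mixtures (equal- and free-variance, G = 1..9) by
   EM; the Bayesian Information Criterion (maximised form, `2·loglik −
   k·log n`) selects the component count. An axis is flagged *dimorphic and
   size-independent* when G = 2 and the Pearson correlation of its scores with
   log CS is non-significant.
5. **Shape reconstruction.** Cluster mean shapes along the dimorphic axis, and
   template-mesh warping onto the consensus or cluster shapes (PLY export).
6. **Element accounting.** Minimum numbers of elements (MNE) per
   element/side/portion, staged specimen-filter ledgers, and the minimum
   number of individuals (MNI) as `max over (side, portion) of fragment MNE +
   same-side complete MNE`.

## Worked example

```python
from osteomorph import (PopulationSpec, RunConfig, build_ideal_femur,
                        run_pipeline)

template = build_ideal_femur()                 # 619-point parametric femur + mesh
config = RunConfig(population=PopulationSpec(n=40, seed=0), seed=0)
report = run_pipeline(config, template=template, outdir="out")

print(report["complete"]["flagged_axes"])      # [1]
print(report["complete"]["axes"]["1"])
```

prints (abridged):

```
[1]
{'selected_G': 2, 'selected_model': 'equal_variance',
 'mixing_proportions': [0.549, 0.451],
 'allometry_r': -0.18, 'allometry_p': 0.265, 'flagged': True}
```

Read: after relaxation and superimposition of 40 synthetic femora, PC1
(36.6% of shape variance) is best described by **two** Gaussian components in
a roughly 1:1 ratio, and its scores do not correlate with log centroid size
(p = 0.26) — a size-independent dimorphism. Against the generator's hidden
morph labels the cluster assignment is 97.5% correct, and the distal-epiphysis
fragment analysis assigns all 40 shared specimens to the same clusters as the
complete-femur analysis (`report["fragments"]["distal"]`).

The same run is available from a shell:

```sh
osteomorph run out --n 40 --seed 0
```

and stage by stage (`simulate`, `slide`, `gpa`, `pca`, `dimorph`,
`consistency`), exchanging plain CSV/JSON files so digitised real data can be
slotted in at any stage.

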