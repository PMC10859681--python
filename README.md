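# radstab

Radiomics feature stability analysis for contrast-enhanced, actively
contoured MRI lesions.

Quantitative image features ("radiomics") extracted from a tumor region of
interest are only clinically useful if they survive re-measurement: a
different observer, a repeat delineation months later, or a different
segmentation pathway should yield the same feature values. `radstab`
implements a complete test-retest pipeline for 2-D diffusion-weighted-MRI-
style images and measures how three segmentation strategies — manual
delineation, semi-automated geodesic active contours, and the same contour
run on CLAHE-enhanced images — propagate delineation variability into
feature variability. It is written for medical-physics and radiomics
researchers who want every stage (enhancement, segmentation, feature
extraction, reliability statistics) as tested, seeded, importable Python.

Since clinical DWI series cannot ship with a package, a synthetic phantom
module generates the study conditions: bright elliptical lesions with
subject-specific intra-lesion texture on darker backgrounds, Rician noise,
smooth bias fields, and an observer model that jitters lesion boundaries
with smooth angular noise.

## The statistics and algorithms at the core

**CLAHE** (from scratch): per-tile histograms are clipped at a ceiling
`max(CL · n_tile, n_tile / n_bins)` counts per bin, the excess is
redistributed uniformly, tile transfer functions come from the clipped
CDFs and are blended bilinearly between tile centers. `CL = 0.9` is the
default clip limit on an 8×8 grid.

**Geodesic active contour**: a level-set field u (negative inside) evolves
as

    ∂u/∂t = g(I) (κ − c) |∇u| + ∇g · ∇u,     g(I) = 1 / (1 + (λ |∇G_σ∗I|)²)

with curvature κ (= 1/r on a disk), balloon speed c (positive outward),
edge-stopping g, and an optional edge-attraction transport term, run for a
standardized 100 iterations from a region-growing initialization.

**Feature registry**: exactly 36 named features — 21 GLCM (Haralick-family)
texture features on a symmetric, normalized co-occurrence matrix (8 levels,
distance 1, four directions averaged), 6 first-order intensity statistics,
and 9 shape descriptors.

**Reliability**: from the two-way ANOVA mean squares of an n-subjects ×
k-measurements table,

    ICC(A,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E))
    ICC(C,1) = (MS_R − MS_E) / (MS_R + (k−1) MS_E)

binned as Poor (< 0.4), Fair [0.4, 0.6), Good [0.6, 0.75), Excellent
[0.75, 1], with two-sided Wilcoxon rank-sum comparisons between arms
(exact by enumeration for small samples).

## Worked example

```sh
python examples/full_experiment.py
```

runs the three-arm experiment on 15 synthetic subjects, two delineation
sessions each, with 1.5 px observer boundary jitter:

```
mean +/- SD of ICC(A,1) per arm:
  manual     0.363 +/- 0.459
  acm        0.772 +/- 0.205
  clahe_acm  0.769 +/- 0.187

reproducibility bin counts (of 36 features):
           manual  acm  clahe_acm
Poor           20    4          2
Fair            3    5          6
Good            2    5          6
Excellent      11   22         22
```

Reading this: under identical boundary jitter, the manual arm inherits the
jitter directly — 20 of 36 features land in the Poor bin — while both
active-contour arms re-derive the boundary from the image and keep 22
features Excellent. The pairwise rank-sum p-values (printed by the script)
show manual differing significantly from both contour arms. Other examples
cover each capability in isolation: phantom cohorts, CLAHE, segmentation,
feature extraction, and the ICC analysis.

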