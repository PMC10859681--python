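# Methods

## What the pipeline models

The package measures how segmentation variability propagates into radiomics
feature variability. One "experiment" is: a cohort of subjects, each with a
2-D grayscale slice and a lesion; per subject, k repeated delineations
(observers × sessions) per segmentation arm; per delineation, a 36-feature
vector; per feature and arm, an n×k measurement table whose intraclass
correlation summarizes reproducibility. Three arms mirror common practice:
manual delineation, semi-automated segmentation (region growing refined by
a geodesic active contour), and the same contour on CLAHE-enhanced input.

## Synthetic phantoms

Clinical DWI series are not distributable, so the generator emulates their
relevant statistical structure:

- **Geometry/intensity**: a rasterized ellipse (semi-axes a, b, rotation θ)
  of intensity `lesion_intensity` on `background_intensity`, both in [0, 1].
  Cohort defaults: 128×128 px, semi-axes 12–30 px, lesion intensity
  0.6–0.95 on a 0.25 background — lesions of order 500–2500 px², the scale
  at which boundary jitter of a few pixels is a realistic fraction of the
  region.
- **Intra-lesion texture**: a smooth Gaussian random field (unit pointwise
  SD, correlation length 2–6 px, amplitude 0.03–0.15) added inside the
  lesion, with per-subject parameters. Real tumors differ in internal
  heterogeneity; without this, texture features would carry no
  between-subject signal and their ICC would be undefined noise.
- **Noise**: Rician, `sqrt((s+g1)² + g2²)` with g1, g2 ~ N(0, σ²), σ = 0.03
  by default — the magnitude-MRI noise model, Rayleigh at zero signal (the
  generator's noise floor is validated against the closed-form Rayleigh
  mean σ√(π/2)).
- **Bias field**: multiplicative `1 + A·p(x, y)` with p a random low-order
  polynomial normalized to [−½, ½], A = 0.2 — a smooth coil-inhomogeneity
  surrogate.
- **Observer model**: a zero-mean Gaussian radial displacement sampled on
  64 polar angles, smoothed by a periodic Gaussian kernel (correlation
  length 40° by default), renormalized to pointwise SD σ_jitter, and applied
  as an offset to the signed distance from the mask boundary. This
  formulation (rather than re-rasterizing a polar polygon) is exactly
  invertible: σ_jitter = 0 returns the input mask bit-for-bit, for any mask
  shape, which anchors the ICC = 1 end of every calibration curve.

What the phantoms do **not** model: k-space/partial-volume effects, ADC
physics, anatomy around the lesion, non-star-shaped or multi-focal tumors,
and inter-scanner variation. Consequently, passing tests demonstrate that
the pipeline correctly *measures* stability under controlled perturbations —
not that any particular arm would win on clinical images. Notably, on these
sharp-edged phantoms the unenhanced contour arm is already near its ceiling
and CLAHE mainly amplifies noise texture, so the enhanced arm does not
dominate here the way it can on low-contrast clinical data.

## CLAHE

Tiles partition the image (8×8 default, near-equal sizes via rounded
splits). Per tile, a 256-bin histogram over [0, 1] is clipped at
`ceiling = max(CL·n_tile, n_tile/n_bins)` counts — CL is the maximum
fraction of a tile's pixels one bin may hold, so CL = 1 never clips
(degenerating to adaptive equalization) and CL → 0 forces the uniform
histogram, whose transfer function is the identity. Published descriptions
of CL "from 0 to 1" rarely pin this normalization; this one is explicit,
monotone in CL, and matches the behavior of reference implementations that
take a normalized clip limit. Clipped mass is redistributed uniformly;
inside `clahe()` redistribution iterates until the residual excess is below
one count, conserving mass exactly (the one-pass variant is also exposed).
Transfer functions are inclusive CDFs; a tile whose histogram occupies a
single bin gets the identity map, making constant images exact fixed
points. Pixel values are mapped by bilinear interpolation between the four
surrounding tile-center transfer functions, clamped at edges; blending is
applied to offsets from the input so degenerate tiles contribute exactly
zero.

## Segmentation

- **Region growing**: maximal 4-connected component within `tol` of the
  seed intensity (tolerance 0.15 by default on raw [0, 1] images).
- **Level set**: u initialized as the signed Euclidean distance of the
  initialization mask (negative inside) and evolved for a standardized 100
  iterations under `∂u/∂t = g(κ − c)|∇u| + ∇g·∇u`. With this sign
  convention κ = div(∇u/|∇u|) is +1/r on a disk and the pure-curvature flow
  (c = 0, g ≡ 1) shrinks a disk at rate 1/r, which the tests verify against
  the closed form r(t)² = r₀² − 2t to within 5%. The balloon c (+0.5
  default, positive outward) drives fronts across flat regions; the
  transport term ∇g·∇u pulls the front into edge minima and can be disabled
  to drop the edge-attraction behavior.
- **Edge indicator**: `g = 1/(1 + (λ|∇(G_σ∗I)|)²)`, σ = 1.5 px. On
  [0, 1]-normalized images a unit-contrast step smoothed at σ = 1.5 has
  peak gradient ≈ 0.27, so the unscaled canonical form never drops below
  ≈ 0.93 and cannot stop a front; the gain λ (default 10, roughly
  equivalent to computing gradients on a 0–255 scale) restores a usable
  dynamic range. λ = 1 reproduces the canonical form exactly and is what
  the unit tests pin against an independent convolution oracle.
- **Numerics**: explicit time stepping with dt = 0.5/(|c| + 4) (CFL-safe),
  Godunov upwinding for the balloon term, per-component upwinding for the
  transport term, central differences for κ with |∇u| regularized by
  ε = 1e−8, and re-initialization to a distance function every 20
  iterations. Re-initialization quantizes the interface to pixel
  resolution, so sub-pixel-per-cycle motions (very slow curvature flows)
  can stall; tests of pure curvature motion disable it. A front that
  vanishes returns an empty mask with a warning rather than raising.

## Features

The registry is fixed at 36 names: 21 GLCM, 6 first-order, 9 shape. GLCM
features use 1-based level weights, log base 2 (0·log 0 = 0), and the two
inverse-difference variants are kept as homogeneity-I `ΣP/(1+|i−j|)` and
homogeneity-II `ΣP/(1+(i−j)²)`. Quantization is range-relative over the
masked region (8 equal-width levels by default), so adding a constant to
the image leaves all GLCM features unchanged; the co-occurrence matrix is
accumulated symmetrically at distance 1 and features are averaged over the
four directions. Degenerate conventions, chosen so no valid input yields
NaN: constant regions quantize to level 0, GLCM correlation of a
zero-variance matrix is 1, information measures fall back to 0 when their
normalizers vanish, first-order skewness/kurtosis of a zero-variance region
are 0 (kurtosis is otherwise not excess-corrected; variance is population).
First-order energy is Σv² on raw intensities; entropy uses a 64-bin
histogram. Shape descriptors use the moments-equivalent ellipse and convex
hull as implemented by `skimage.measure.regionprops` (perimeter uses its
standard weighted boundary approximation), with orientation reported in
degrees in (−90, 90] from the row axis; the equivalent diameter is
√(4·area/π).

## Reliability statistics

Mean squares come from the standard two-way decomposition; interaction
residuals are computed directly (t − row − col + grand) rather than by
subtracting sums of squares, so identical-column tables give MS_E = 0
exactly and ICC = 1 exactly. ICC(A,1) (absolute agreement) and ICC(C,1)
(consistency) follow the single-measurement two-way forms above. Notable
properties, all tested: both are invariant to common affine transforms and
subject relabeling; C,1 is invariant to per-column shifts while A,1 is
penalized by them; and C,1 ≥ A,1 holds exactly in the regime
MS_C ≥ MS_E and MS_R ≥ MS_E — outside it (rater variance below interaction
variance, or negative ICCs) the ordering genuinely reverses, a fact easy to
miss because applied papers usually quote the inequality unconditionally.
An all-identical table is reported as ICC = 1 with a degeneracy flag (the
perfect-reproducibility limit of deterministic re-extraction). A
`printed_formula=True` mode reproduces a garbled published variant of both
formulas — (k+1)·MS_E in the agreement denominator, MS_W numerator with a
(k−1)·MS_R denominator term for consistency — for auditability only; it is
not a recognized estimator and fails the identical-columns → 1 sanity case
(giving 1/k instead).

Bins use half-open intervals [0, .4), [.4, .6), [.6, .75), [.75, 1] so
every value lands in exactly one group; published bin labels overlap at the
cut points and this resolution preserves their labels at all non-boundary
values. Negative ICCs bin as Poor; values above 1 are rejected.

The rank-sum test enumerates all C(n, n_x) rank assignments (with midranks,
which keeps the enumeration valid under ties) when n_x + n_y ≤ 12, and
otherwise uses the normal approximation with tie and continuity
corrections. Arm summaries report mean ± population SD of per-feature ICCs.

## Experiment driver

All randomness flows from one global seed through CRC-derived per-(stage,
subject, observer, session) seeds, so results are independent of execution
order and reruns are byte-identical (hashes recorded in the run manifest).
In the contour arms, observer variability enters through the
initialization: the observer's jittered delineation seeds region growing
(falling back to a small disk if growth collapses or escapes), and the
contour re-derives the boundary — which is precisely the mechanism by which
semi-automated segmentation buys reproducibility. Features in the enhanced
arm are extracted from the enhanced image.

## Problem sizes

Defaults used by the test suite and the acceptance script: 30-subject
cohorts at 128×128 px with 2 sessions for stability studies; 20 phantoms
per condition for segmentation recovery; 1000 random tables / 100 random
matrices / 1000 random histograms for the estimator and CLAHE checks. These
sizes give stable Monte-Carlo margins (e.g. the jitter-monotonicity
fraction is 100% across seeds) while a full run of everything stays within
tens of seconds.

## Known limitations

- 2-D only; no 3-D volumes, wavelet/LoG feature classes, or full IBSI
  conformance audit.
- The observer model displaces boundaries along the signed distance, so it
  cannot split a lesion or create satellites.
- ICC confidence intervals and REML variance components are out of scope;
  estimators are moment-based.
- The level-set scheme is explicit and single-resolution; very slow flows
  interact with re-initialization as described above.
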