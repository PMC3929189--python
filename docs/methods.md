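# Methods

This note documents the models and numerical choices behind wbckit, the
assumptions they rest on, and what the synthetic test bed does and does
not demonstrate about real smear images.

## HSI color model

All stages share one HSI convention: the arccos (chromatic-angle) model
with hue in degrees on [0, 360), saturation and intensity on [0, 1],
computed in double precision and never quantized. Achromatic pixels
(R = G = B) are assigned H = 0 so the conversion is total and
deterministic; hue is folded to the half-open range. The inverse
conversion (used only by the scene generator) is the standard three-
sector construction.

The two shipped preset regions were published without any statement of
the HSI scaling they were fitted under, and their constants (e.g. a hue
center of 6.042 beside semi-axes above 50) cannot be reverse-engineered
to a scaling. They are therefore stored exactly as printed and tagged
`convention_tag="paper-unknown"`; regions fitted by this package carry
`"gw-degrees-unit"`. `classify_pixels` assumes the caller matched image
and region conventions. The printed preset matrices are also not
orthonormal to printed precision (row-1 norm of the first preset is
about 1.033); they are deliberately not re-orthogonalized, and the
center pre-image is computed with the true matrix inverse rather than
the transpose so the membership-at-center = 0 contract holds exactly for
presets and fitted regions alike.

## Discriminating-region fitting

PCA on the sample covariance gives the rotation (rows = eigenvectors,
sorted by descending eigenvalue). Eigenvector sign is fixed by making
each row's largest-magnitude entry positive; this can produce a
left-handed orthonormal frame, which is an equally valid change of basis
for the quadratic form and is accepted as-is.

Semi-axes must be inferred from the samples; the procedure is a
per-axis quantile rule — r_k = (coverage^(1/3))-quantile of the absolute
centered projection along axis k — followed by one global multiplicative
correction, found by bisection (200 iterations, bracketing doubled until
feasible), so that the fraction of samples with membership ≤ 1 matches
the requested coverage within ±0.5%. The per-axis step shapes the
ellipsoid to the cloud's anisotropy; the global step makes the coverage
exact. Default coverage is 0.975.

Hue is treated as a linear scalar throughout (no circular statistics).
This matches how such regions are used in practice but will misbehave
for tone clusters straddling the 0/360 wrap; the stains this pipeline
targets sit far from the wrap (purple, H ≈ 270–330).

Degenerate inputs: fewer than 4 samples, or a covariance of rank < 3,
raise immediately rather than producing a flat ellipsoid.

## Segmentation

Raw masks mark membership ≤ 1. Refinement applies, in order: 3×3 square
dilation, 3×3 square closing, 7×7 median filter, hole filling, then
keeps only the largest 8-connected component (holes are re-filled after
selection so the output contract — at most one component, no interior
holes — holds unconditionally). The 3×3 elements are the smallest
standard choices that close single-pixel breaks; all sizes are keyword-
configurable, including disabling hole filling. Rates with zero
denominators are defined as 1 (an image with no positives to find is
vacuously perfectly handled); this convention is part of the API.

The dilation step biases the refined mask outward by 1–2 px, which
trades a small specificity cost for sensitivity ≈ 1 on clean scenes.

## Features

* Boundary pixels are foreground pixels 8-adjacent to background or to
  the image edge; the perimeter is the boundary-pixel count, and
  boundary lengths are Euclidean distances to the foreground centroid.
  This estimator is simple and exactly testable, but it carries a known
  jaggedness bias: a digital disk has ≈ 8r boundary pixels against a
  true perimeter of 2πr (ratio ≈ 1.27), so at equal area a digital
  square scores *lower* compactness (≈ 15.7) than a digital disk
  (≈ 20.1). The feature still separates blocky from elongated and lobed
  shapes, which is what the classifier consumes; absolute values should
  not be compared against continuous-geometry formulas.
* All variances (boundary lengths, H/S/I over the cell) are population
  variances (divide by N).
* LDP: the grayscale input is ITU-R 601 luma; the 8 Kirsch masks are the
  45° rotations of the east template [[−3,−3,5],[−3,0,5],[−3,−3,5]],
  applied as cross-correlation; directions are ranked by absolute
  response (the convention of the LDP literature), ties broken toward
  the lower direction index, and the top 3 set bits of the code. Codes
  are computed for in-mask pixels whose 3×3 neighborhood lies inside the
  image; everything else is a sentinel. The full histogram spans codes
  7..224 (218 bins, 56 of them realizable); the reduced descriptor reads
  the 14 bins that dominated stained-leukocyte texture in the original
  60-image calibration. That calibration data is not redistributable,
  so the bin list ships as the frozen default while
  `select_prominent_bins` (average raw counts above a threshold)
  reproduces the selection procedure on any corpus.
* Feature order is frozen (version 1) and written into CSV headers so
  trained models remain portable.

## Classifiers

All three consume the 20-feature vector and emit one of the five
leukocyte classes.

**MLP** — 20×12×10×5, logistic hidden activations, z-scored inputs,
Adam backpropagation (scikit-learn engine), epoch-capped, fully
deterministic given the seed. The stored model is just the weight
matrices; inference is a self-contained forward pass (argmax readout;
for a binary head, the sign of the single logit with scikit-learn's
orientation).

**SVM** — RBF kernel, one-vs-one, z-scored inputs, C = 10, gamma =
"scale" by default. The stored model is the support vectors, dual
coefficients and intercepts; inference replays libsvm's pairwise voting
(first maximum wins ties), verified prediction-identical to the fitting
engine on random probes.

**HRCNN** — hidden node j fires when Σ_i f((M_ji − x_i)(x_i − m_ji)) − n
≥ 0 with f the Heaviside step, i.e. exactly when x lies in the closed
box [m_j, M_j]; a class fires when at least one of its boxes does
(η = 0.5; any η in (0, 1) is equivalent for binary hidden outputs).
Training is sequential covering: points are visited in input order (a
seed-controlled shuffle is optional); a covered point is skipped; an
uncovered point first tries a minimal expansion of each existing
class box, accepted iff the expanded box contains no other class's
training point; otherwise it starts a degenerate box. Every training
point ends covered and no box contains a foreign point, so training
accuracy on consistently labeled data is 100% by construction;
contradictory duplicates raise. Inference conflicts are resolved
deterministically: several firing classes → the class of the smallest
(range-normalized) containing box, the most specific rule; no firing
class → the class of the box nearest in range-normalized Euclidean
distance to its surface. Boxes are stored in original feature units so
the If-Then rules list the synaptic weight intervals verbatim; the
min-max ranges recorded at training time only normalize the tie-break
geometry, leaving containment — and hence Eq.-style semantics —
untouched.

## Synthetic data

The scene generator emulates exactly the properties the pipeline is
sensitive to: a pale jittered background far outside the tone region;
elliptical cells whose per-pixel tones are drawn from a Gaussian in the
region's rotated frame (σ = semi-axis/2) truncated to a membership cap
(sampled exactly via a uniform direction and an inverse-CDF chi(3)
radius, which stays O(n) even as the cap → 0); optional red granule
disks inside the cell (the occlusion mechanism by which heavily granular
basophils defeat color-based segmentation — sweeping granule density
produces a monotone sensitivity collapse); and isolated cell-tone
speckles on the background. The default scene places one cell of axes
(22, 18) px in a 120×120 frame — a cell diameter about a third of the
frame side, matching the proportions of single-cell smear crops this
kind of system processes. Ground truth is the exact ellipse
rasterization, so segmentation scores carry no annotation noise.

What the generator does **not** model: touching or overlapping cells,
red blood cells and platelets, uneven illumination, stain batch
variation, chromatic camera noise, or hue wraparound tones. Passing the
end-to-end tests therefore demonstrates the pipeline's correctness and
its behavior under controlled degradation, not clinical-grade accuracy
on real smears.

The feature-set generator produces 5 Gaussian clusters in the 20-feature
space, mapped to plausible scales (positive areas, LDP frequencies in
[0, 1]). "Separation" is defined as the distance of each centroid from
the shared feature-space center, in per-feature σ units, along mutually
orthogonal directions (pairwise centroid distance = separation·√2).
The radius definition was chosen over pairwise distance because in 20
dimensions clusters of radius ≈ √20 σ at pairwise distance 5σ
interpenetrate enough that even a nearest-neighbor oracle tops out near
90% held-out accuracy; at radius 5σ the conditions behave as
"well-separated" clusters should — chance-level performance at
separation 0, perfect HRCNN training at separation 5, and ≥ 95%
held-out accuracy for all three classifiers.

## Problem sizes

The test suite and the acceptance script run at deliberately modest
sizes chosen as sufficient for their statistical claims: 120×120 scenes,
10⁴-sample fitting clouds, 250–400-vector classifier datasets, and
10⁴-point oracle equivalence probes. Fitting-recovery tolerances (10%
on axis ratios from dense clouds, 15% from membership-truncated
samples) reflect the quantile estimator's variance at those sizes.
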