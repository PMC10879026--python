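# Methods

This note documents the models and procedures implemented in `rbcdetect`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Synthetic scenes

The generator (`rbcdetect.synthetic`) emulates the geometry of stained
blood-smear fields rather than their optics: cells are ellipses with a
raised-cosine rim (edge width 1.5 px) composited onto a background with a
gentle horizontal intensity gradient, followed by multiplicative speckle
and additive Gaussian noise, clipped to [0, 1]. Cells are darker than the
background by default (cell intensity 0.35 on background 0.85), matching
the convention that thresholding labels low intensities as foreground;
bright-cell imagery is handled by a polarity switch in the segmenter.

Standard conditions, chosen once: 256×256 fields with 20 cells of radius
8–12 px and Gaussian noise σ = 0.02 for segmentation studies; 64×64
fields with 5 cells of radius 5–9 px, overlap fraction 0.2 and background
gradient 0.05 for detection studies. These sizes keep a full train/evaluate
cycle in the tens of seconds on one CPU while leaving cells touching often
enough to exercise the hard case.

Placement: non-cluster cells are rejection-sampled (retry cap 1000,
explicit error on infeasible packing) with a 4 px clearance margin beyond
the sum of radii, which keeps components separable through a 3×3 dilation.
Cluster members are placed at 0.6–0.95 of the sum of radii from a host
cell; each member marks itself and a previously isolated host as
"involved", so the fraction of cells with a touching neighbour tracks the
requested overlap fraction (tolerance ±0.1). Every scene carries its
instance mask, and each ground-truth box is by construction the tight
bounding box of its mask component.

What passing tests on these scenes do *not* show: robustness to staining
variation, uneven illumination beyond a linear ramp, debris, out-of-focus
blur, or the morphology of white cells and platelets. The noise model is a
stand-in, not a measurement of any real instrument.

## Bilateral filtering and the radial gradient index

The filter computes, at each pixel,
`I'(i,j) = Σ w(i,j,p,q) I(p,q) / W(i,j)` with
`w = exp(−((i−p)²+(j−q)²)/2σ_d²) · exp(−(I(i,j)−I(p,q))²/2σ_r²)`.
As written the sum ranges over the whole image; the implementation
truncates the window at radius ⌈3σ_d⌉ (configurable), where the spatial
weight has decayed below 1.2 %. Neighbourhoods are clipped at image
borders with no padding; the normalizer `W` adapts, so the output is
always a convex combination of input values and stays inside
[min I, max I]. The brute-force test oracle uses the same window, making
the equivalence check exact (1e−10). Iterated application stops at
`n_iterations` (default 1, maximum useful ≈ 10) or when the mean absolute
per-pixel change falls below `convergence_tol` (default 1e−4). Defaults
σ_d = 1.5 px, σ_r = 0.1 intensity units suit the normalized scenes here:
σ_r is about twice the noise level yet well below the ≈ 0.5 cell/background
contrast, which is what preserves rims while flattening noise.

The radial gradient index of a disc (center c, radius r) is the mean over
disc pixels of the cosine between the local intensity gradient
(`numpy.gradient`) and the **outward** radial direction; pixels with zero
gradient contribute 0, and an all-zero-gradient disc scores 0 by
convention. A radially symmetric dark-center cell, whose intensity rises
outward, scores ≈ +1; noise-dominated background scores ≈ 0. The cosines
are deliberately *not* weighted by gradient magnitude: weighting lets the
one-sided gradient tail dominate when the disc sits off-center on a blob,
producing strongly negative scores where a location-discriminating score
should be near zero (measured: ≈ −0.55 at a 3-radius offset, versus
≈ +0.11 unweighted). A magnitude-weighted variant remains available via a
flag.

## Threshold and morphology segmentation

Otsu's between-class-variance maximization over a 256-bin histogram picks
the threshold by default (a fixed value may be supplied); a constant image
has no threshold and raises. The split assigns `I ≤ T` to foreground —
boundary pixels are foreground. Erosion/dilation take the min/max over a
structuring element (default 3×3 square, origin required); out-of-bounds
neighbours count as 0 for *both* operations, a deliberate symmetric
convention, so erosion/dilation duality is asserted on interior pixels
only. The combination rule `R = dilate(F) ∧ ¬ erode(B)` is implemented
exactly as stated, including its truth table; a conventional
opening/closing alternative was considered and rejected to keep the
printed rule testable as-is. Counting uses 8-connectivity with a 30 px
minimum area (well below the ≈ 200 px area of the smallest default cell,
large enough to kill noise specks).

Touching cells are *not* split (no watershed/distance transform); a
cluster counts as one component. This is a known limitation, which is why
count-recovery benchmarks use non-overlapping scenes.

## The region-proposal detector

The detection pipeline is the classical two-stage recipe: anchor lattice →
RPN scoring/regression → clip to image → minimum-size filter → stable
descending score sort with `pre_nms_topN` (default 6000) → greedy NMS at
IoU 0.7 keeping `post_nms_topN` (default 300) → RoI max-pooling → a
classification + box-refinement head → per-class NMS at IoU 0.3 → score
threshold (default 0.5).

Feature extraction is a fixed, deterministic convolutional bank rather
than a learned deep backbone: Gaussian-smoothed intensity; one
scale-normalized Laplacian-of-Gaussian channel per anchor scale
(σ = scale / 2√2, the classical matched blob detector, positive at dark
blob centers); Gaussian x/y derivatives at σ = 1.5 and 3 (these encode the
sub-stride offset to the nearest blob center, which is what makes linear
box regression work); gradient magnitude; and a wide local mean. The RPN
and RoI heads are linear models on standardized features, trained from
scratch with a hand-written full-batch Adam loop (500 and 400 steps, lr
0.05). This keeps the whole detector dependency-light, CPU-fast, and
bit-reproducible from a single seed, at the cost of the representational
power a trained deep backbone would bring on real imagery — adequate here
because synthetic cells are blob-shaped by construction.

Anchor defaults: stride 8, scales {12, 20, 32} px, ratio {1.0} (cells are
round; a ratio r stretches to w = s√r, h = s/√r, preserving area). Target
assignment: positive at IoU ≥ 0.7 or best-anchor-per-truth (forced
positives require IoU ≥ 0.1 — below that the configured scales cannot
represent the object and training aborts with a diagnostic); negative at
IoU ≤ 0.3; the rest ignored; negatives are subsampled to 3× the positives.
Box regression uses the standard parameterization (center offsets
normalized by anchor size, log width/height ratios). The multitask loss is
cross-entropy plus λ·smooth-L1 (λ = 1, β = 1) summed over the 4 box
coordinates and averaged over positives; the localization term is 0
without positives. The RoI head pools a 6×6 grid from a stride-2,
3-channel fine map over each proposal, and is trained on RPN proposals
plus jittered ground-truth boxes (positives at IoU ≥ 0.5, negatives
< 0.3).

RoI pooling rounds each region outward to whole cells, splits it into an
output grid via floor-of-linspace bin edges, and takes the per-bin max;
degenerate bins yield 0 and are logged. Tie-breaks everywhere are by
original index (stable sorts), so results are exactly reproducible.

Model checkpoints are `.npz` (version field, constructor parameters as
JSON, weight arrays); the format is versioned and loading rejects unknown
versions.

## Post-processing and labeling

Detections can be filtered by the conjunction of: score ≥ 0.5, center-disc
RGI ≥ 0 (disc radius = half the smaller box side), and area within
[0.25, 4]× the median detected area. The final label mask is the set union
of surviving boxes (half-open, rounded). Region ranking combines min-max
normalized detector score, RGI and box-counting fractal dimension with
weights (0.6, 0.3, 0.1); the order score → RGI filter → rank is a
convention. The fractal dimension is the least-squares slope of
log N(s) vs log(1/s) over dyadic box sizes from 1 to half the enclosing
power-of-two square, clipped to [0, 2]; filled cells score ≈ 2, thin
artifacts ≈ 1, and a patch with no countable structure scores 0. It is a
plausibility feature only.

## Evaluation protocol

Predictions are matched greedily in descending score order to the
highest-IoU unmatched truth at IoU ≥ 0.5 (greedy, not Hungarian — the
standard in detection benchmarks). Reported metrics: precision, recall,
F1, and a detection accuracy TP/(TP+FP+FN); zero denominators give 0 with
a degenerate flag. Both a 60/20/20 holdout (remainders to train) and
k-fold cross-validation (default k = 10, fold sizes within 1) are
provided; no claim is made about equivalence to any particular published
protocol, whose accuracy metric is not defined in enough detail to
reproduce. A 24×24 patch extractor is provided for per-region
classification heads.

## Numerical and degenerate-case conventions

- Boxes are half-open `[x0,x1)×[y0,y1)`, 0-based; zero-area boxes have
  IoU 0 by definition.
- Constant-image normalization maps to all zeros (avoids 0/0).
- NMS discards on IoU strictly greater than the threshold; score ties
  keep the lower original index.
- All randomness flows through `numpy.random.default_rng(seed)`; fixed
  seeds give bit-identical scenes, transforms, splits and training
  trajectories.

## Known limitations

- No splitting of touching/overlapping cells; clusters merge in both the
  segmentation count and, partially, in detection.
- The fixed feature bank is matched to blob-like dark cells; heavily
  textured or irregular cells would need a learned backbone.
- Augmentation parameter semantics follow the common image-generator
  convention (rotation in degrees, shifts as fractions, zoom 1±range,
  intensity rescale 1/255); boxes are transformed as axis-aligned hulls
  of warped corners, which slightly over-covers under large rotations.
- Synthetic benchmarks bound correctness, not clinical performance.
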