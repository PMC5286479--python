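# Methods

## Problem setting

Retinal fundus photographs show the vessel tree as dark curvilinear
structures on a brighter, unevenly illuminated background, inside a roughly
circular field of view (FOV). The package frames segmentation as binary
classification of individual FOV pixels: a hand-designed 23-component
descriptor per pixel, an RBF-SVM, and a morphological postprocessing step.
All computation runs on the green channel, which carries the strongest
vessel/background contrast, kept on the native 0–255 scale so that the
intensity threshold *S* is expressed in 8-bit grey levels. Coordinates are
row-major, 0-based (row, col), row axis downward.

## Line-set shape features

From each pixel, 24 rays are traced. A ray at angle (k − 1) · 15° from the
+x axis (k = 1..24, counter-clockwise; rows increase downward) is sampled
at unit Euclidean steps, each sample rounded to the nearest pixel with
halves away from zero, consecutive duplicates collapsed. Rays 13–24 are
built as exact pixelwise mirrors of rays 1–12: floating-point trigonometry
is not exactly odd, and without this construction opposite rays can differ
by one pixel where a coordinate lands on a half-integer. Path length counts
distinct pixels including the seed, so lengths lie in [1, cap].

Tracing stops at the first pixel that (a) leaves the image, (b) leaves the
FOV, or (c) differs from the **seed** pixel by ≥ *S* grey levels.
Seed-anchored comparison is the default because vessels are locally
homogeneous and anchoring prevents slow drift across a soft edge; a
previous-pixel comparison mode (`LineSetConfig(compare="previous")`) exists
for sensitivity analysis. Since the stopping rule does not depend on the
cap, the 21-px line set is a prefix of the 41-px one and both are computed
in a single whole-image sweep.

Per line set the features are f₁ = LL, f₂ = LP, f₃ = LL − LP,
f₄ = LL − AL/24, f₅ = AL/24 − LP, f₆ = R_L + R_P, f₇ = |SNLL/8 − LL|,
f₈ = |SNLP − LP|. Conventions adopted where more than one reading is
possible:

- Ties for longest/shortest segment break toward the lowest direction
  index, making the main direction deterministic.
- R is computed for the longest and shortest segments only (R_L, R_P),
  each as (path pixels sharing the seed's main direction)/length.
- f₇ divides SNLL by 8; f₈ uses SNLP undivided. The asymmetry is kept
  deliberately — the two features have different magnitude scales, and the
  per-image normalization removes any scale advantage either way.
- 8-neighbours outside the image or FOV contribute 0 to SNLL/SNLP while f₇
  keeps its fixed /8 denominator; this affects only FOV-border pixels.

f₃ = f₄ + f₅ holds algebraically; the test suite asserts it at 1e-9 on
random phantoms. Since LP ≤ AL/24 ≤ LL, f₄ and f₅ are nonnegative by
construction.

The fan geometry treats "24 directions" as full 360° coverage at 15° ray
spacing: a 7.5° spacing over 24 rays would span only a half-plane and could
not distinguish a pixel just above a vessel from one just below. The angle
step is configurable, so the 7.5° half-plane variant remains available.

## Local intensity and morphological gradient

Window means over L × L squares, L ∈ {3, 5, 11, 21, 31, 41}, are computed
with an integral image; windows are clipped at the image border (mean over
in-bounds pixels), which is exact and avoids inventing padding values. For
integer-valued 8-bit images the integral-image sums are exact in float64.

The gradient feature is the mean over disk radii 1..6 of grayscale dilation
minus erosion. The disk dᵢ is the discrete set {(dr, dc) : dr² + dc² ≤ i²}.
Borders use reflect padding so the FOV boundary does not generate spurious
edge responses. The feature is invariant to adding a constant and scales
linearly with contrast (both property-tested).

## Descriptor and normalization

Component order is fixed: 8 line-set-one features, 8 line-set-two features,
6 window means (ascending L), gradient — 23 in total. Each component is
standardized to zero mean and unit variance over the image's own FOV pixels
(zero-variance components map to 0); test images use their own statistics.
Per-image standardization is chosen over pooled statistics because its
purpose is precisely to cancel inter-image illumination and contrast
differences; min–max scaling is available behind a flag.

## Classifier

20 000 pixels per training image (default) are drawn uniformly without
replacement from the FOV, keeping the natural ≈ 12% vessel prevalence; a
stratified option is deliberately absent from the default path. The SVM
uses an RBF kernel with C = 1 and γ = 0.01. When `grid_search=True`,
(C, γ) is selected by 5-fold cross-validated accuracy over
C ∈ {0.1, 1, 10, 100} × γ ∈ {0.001, 0.01, 0.1, 1}, ties broken toward
smaller C then smaller γ via grid iteration order. Scores are raw SVM
decision values — signed distances to the separating surface — rather than
probabilities: the postprocessing thresholds (0, then T ≈ 0.2–0.35) only
make sense on a signed scale where 0 is the class boundary. A
Platt-calibrated probability map is available behind `probability=True`
for visualization, but no pipeline stage consumes it.

## Postprocessing

Mask = {score > 0} ∩ FOV, marker = {score ≥ T} ∩ FOV, output = union of
the 8-connected components of the mask that contain a marker pixel. The
base cut is strict so that a pixel exactly at the boundary does not count
as vessel and the step is idempotent when fed an already-binarized map.
8-connectivity is the default because vessels are thin and frequently
diagonal; 4-connectivity would sever diagonal links (configurable).
Component filtering is provably the fixed point of binary
geodesic dilation of the marker under the mask; the equivalence against a
grayscale-reconstruction implementation is asserted in a test. Guaranteed
laws (property-tested on 200 random score fields): marker ⊆ output ⊆ mask,
whole-component preservation, monotonicity in T, idempotence.

T defaults to 0.2; a 0.35 constant is provided for DRIVE-style material
where the decision-value distribution sits higher. Raising T only removes
components, so it trades sensitivity against noise suppression.

## Evaluation

TP/FP/TN/FN are counted over FOV pixels only and always sum to the FOV
size. ACC = (TP+TN)/FOV, SEN = TP/(TP+FN), SPE = TN/(TN+FP); SEN or SPE is
reported as missing when its denominator is zero rather than coerced to a
number. Means across images are unweighted. Experiment drivers cover
leave-one-out, cross-dataset training and a sweep of *S*.

## Synthetic phantoms

A phantom is: background 180 plus a smooth three-harmonic illumination
field of peak amplitude 15; six vessels whose centerlines are
bounded-curvature random walks (heading noise sd 0.03 rad/step) entering
from the FOV rim, dilated to widths 1–7 px (within the 1–15 px range of
real vessels) and rendered 40 grey levels darker; Gaussian noise sd 3,
clipped to [0, 255] and rounded to integers (the feature math presumes
8-bit quantization); circular FOV of radius 0.94 · (size/2). These defaults
put the vessel fraction at 9–15% of the FOV across seeds, matching the
10–15% prevalence of expert-annotated fundus datasets, with contrast ≫ S
and noise ≪ S so that an interior centerline ray of a straight vessel runs
to the 21-px cap. Everything is deterministic given the spec's seed.

Phantoms have no optic disc, fovea, branching topology, central vessel
reflex, or pathology, and their noise is i.i.d. rather than textured.
Passing phantom tests therefore demonstrates that the pipeline's mechanics
are correct and self-consistent — not that clinical-grade accuracy carries
over to real retinas, which requires the real datasets and the provided
loaders.

## Problem sizes and numerical choices

The default test suite and worked example run on 64–256 px phantoms: the
end-to-end recovery check trains on four 256×256 phantoms (20 000 samples
each) and segments a fifth, which takes well under a minute on one CPU;
brute-force oracle comparisons use 64×64 images where exhaustive per-pixel
recomputation is cheap. Intensities and line lengths are small integers,
so all feature arithmetic is exact in float64 except the agreement ratios
and normalization, which are compared at 1e-9. Degenerate inputs are
handled explicitly: empty FOVs, single-class training sets, empty markers,
zero-variance descriptor columns, and windows clipped at borders.

## Known limitations

- Whole-image line-set tracing is O(H · W · 24 · 41); a 605×700 fundus
  image takes a few tens of seconds per image in pure numpy.
- The seed-anchored stopping rule can overrun a slow-ramp edge of total
  swing < S; the previous-pixel mode is more conservative there but drifts
  across soft edges.
- No illumination correction or CLAHE is applied by design; severely
  non-uniform images rely entirely on the per-image normalization.
- Hyperparameter search re-fits on pooled training pixels; it does not
  nest the per-image sampling inside the folds.
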