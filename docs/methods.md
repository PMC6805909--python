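# Methods

`shellfeat` turns a pair of photographs of a mollusc shell — a frontal
view (A) and a lateral view (B) on a near-black background, canonically
300×400 px — into a fixed-length feature vector, and evaluates how well
those vectors separate species under a repeated-holdout protocol. This
note records the model, the numerical choices, and what the synthetic
test bed does and does not demonstrate.

## Background segmentation

The photographic background is delimited by flood fill grown from the
four image corners, 4-connected. A pixel is absorbed when its maximum
channel value is at most the tolerance (default 10 of 255, absorbing
JPEG ringing around true black) or when it is within the tolerance of
the corner seed colour in every channel. Four corners make the
segmentation robust to a specimen touching one border; 4-connectivity
is conservative in that the fill cannot leak through diagonal gaps. The
shell mask is the complement reduced to its largest connected component
with interior holes filled, so boundary tracing always sees one closed
contour. Resizing to the canonical frame is bilinear and forces the
aspect ratio; the downstream features are insensitive to the
interpolator at the tolerances tested.

## Colour: histogram moments (12 values)

Per view, R/G/B histograms (256 bins) are accumulated over foreground
pixels only; the two views give a 256×6 count matrix. Each column is
summarized by its histogram-weighted mean and standard deviation —
12 values on the 0–255 intensity scale. The standard deviation is the
population form (divide by N): the histogram summarizes the complete
pixel set of the specimen rather than a sample from it; a `ddof` switch
provides the N−1 form. Masking before binning (rather than subtracting
background counts from bin 0 afterwards) is exactly equivalent for a
pure-black background and strictly more correct for near-black noise.

## Shape: centroid contour distance (72 per view, 144 per sample)

The outer contour is traced from the shell mask by Moore-neighbour
tracing, yielding an ordered closed polyline of border-pixel centres
(counter-clockwise in the shared x-right/y-down frame). The area
centroid of that polygon comes from the shoelace formula. A ray is then
cast from the centroid every 5° (0° along +x), and the distance to the
*farthest* intersection with the boundary polygon is recorded — the
farthest crossing follows the outer silhouette and is stable under
small interior concavities. 72 distances per view, concatenated A then
B into 144 values, in pixels, deliberately unnormalized (acquisition
fixes the scale).

Numerical choices: ray–segment intersections are solved in closed form
with a 1e-12 parallelism guard; a ray that misses every segment (only
possible through floating-point corner cases) falls back to the
boundary vertex nearest in angle, never NaN. A centroid falling outside
the polygon (extreme concavity) raises an error with a diagnostic
rather than producing a silently wrong profile. Contours need at least
3 points; single-pixel masks are rejected.

## Texture: Gabor-bank patch statistics, PCA to 10

The bank holds 20 complex Gabor filters — orientations
{0°, 45°, 90°, 135°} by frequencies {5, 10, 15, 20, 25}. A filter is
the unit-normalized Gaussian envelope times the complex carrier
`exp(jω(x cosθ + y sinθ))`, sampled on an odd K×K grid with
K = 2·ceil(3·max(σx, σy)) + 1, so the centre value is 1/(2π σx σy).
Two conventions are deliberate defaults, both configurable:

* **Frequency units.** The printed values are interpreted as cycles per
  20-px patch width, i.e. ω = 2πf/20 radians per pixel, which places
  all five wavelengths (4 px to 20 px) inside a patch.
* **Spatial width.** σx = σy = π/ω, so the envelope (±σ) spans about
  one carrier period.

From the frontal view, 200 patches of 20×20 px are drawn uniformly with
replacement from all placements fully inside the shell mask
(deterministic per seed). Each of the 200×20 = 4000 responses — the
same-size zero-padded convolution of the grayscale patch with the
kernel — is summarized on its magnitude by average Σ|r|/400, energy
Σ|r|²/400, and entropy −Σ p·log p with p = |r|/400, natural log and
0·log 0 := 0. Magnitudes are used for all three statistics for internal
consistency with the complex kernel. Each statistic column of the
4000×3 matrix is sorted ascending, which makes the descriptor invariant
to the patch sampling order.

The sorted matrices, flattened to 12 000 values, are compressed by PCA
(centred SVD) to the 10 leading scores. By default the PCA is fitted on
the training rows of each evaluation split and used to project both
sides (no test-set leakage); `pca_scope='all'` fits once on every
sample, matching a fixed published feature table. If a training set
carries fewer than 10 variance directions, trailing components are zero
vectors so the score length stays 10. Component signs follow the
largest-|loading|-positive convention for reproducibility.

## Evaluation protocol

Combined vectors are colour ⧺ shape ⧺ texture = 12 + 144 + 10 = 166
dimensions. Per repetition a stratified split sends round(0.7·n_c)
samples of each class to training (7 of 10 in the default design), the
rest to test. k-NN uses Euclidean distance on raw features (optional
z-scaling exists but is off by default); vote ties are broken by the
tied class with the nearest member. The random forest is the standard
bagged-trees/√d-features-per-split classifier (scikit-learn under the
hood), seeded per repetition. Scores are accuracy, micro-F1 — computed
from class-summed TP/FP/FN, and identically equal to accuracy in this
single-label multiclass setting — and macro-F1, the unweighted mean of
per-class F1, which is the averaging that can genuinely differ.
Defaults: 30 repetitions; means are reported with Student-t 95%
confidence-interval half-widths (a single repetition reports 0 with a
warning). Parameter sweeps rerun the protocol over a grid of k or tree
counts and report the argmax by mean accuracy.

## Synthetic test bed

The generator emulates the two-view acquisition: a star-convex polar
outline r(α) = R(1 + A·cos(mα)) with A ≤ 0.3 (guaranteeing the centroid
is interior and every ray crosses the boundary once), a base colour
modulated by horizontal sinusoidal stripes, Gaussian pixel noise
(default σ = 6 intensity levels, a realistic sensor-noise scale),
pure-black background, and a lateral view at 0.8 relative scale with an
independent noise draw. The default grid is 10 species × 10 samples;
species differ jointly in hue, outer radius (R(1+A) fixed at one of
70–130 px so every outline fits the frame), lobe shape and stripe
period, cycled through coprime-length lists so combinations never
repeat.

Because the outline and colours are known in closed form, the tests can
assert parameter recovery: colour means within the noise level, radial
profiles within 2 px of r(α) at all 72 angles, and texture scores that
separate stripe periods. What the generator does **not** model — and
what passing tests therefore do not show — includes real frontal/
lateral shell geometry (the two views differ only by scale and noise),
within-species morphological variation, illumination and pose
variation, and non-black or cluttered backgrounds. End-to-end 1-NN
accuracy near 100% on this grid demonstrates pipeline correctness and
the built-in class separation, not field performance on photographs.
Non-star-convex shapes are exercised by hand-built masks in the tests
instead of the generator, keeping generated ground truth exactly
computable.

## Problem sizes

The shipped tests and the acceptance script run entirely on generated
data: the default 10×10 grid (100 two-view samples), 30 evaluation
repetitions, and 10 repetitions inside the k sweep. A full run of the
acceptance script takes well under a minute on one CPU.

## Known limitations

* The radial descriptor is scale- and rotation-variant by design;
  specimens must be photographed under the fixed acquisition convention.
* The farthest-intersection rule handles mild concavity only; deeply
  concave silhouettes whose centroid leaves the polygon are rejected,
  not approximated.
* Gabor σ and frequency units are conventions, not measured facts; any
  comparison across configurations must hold them fixed.
* The flood fill assumes the background is near-black and reaches the
  corners; a specimen occluding all four corners would defeat it.
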