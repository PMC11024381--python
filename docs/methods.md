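# Methods

`tepals` estimates the arrangement (aestivation) of a flower's petal-like
perianth organs from a single photograph.  The arrangement is the circular
pattern of which neighboring tepal lies above which; it reflects the order
in which the organs were initiated during development, and scoring it by
eye is specialist work.  The package decomposes the problem into stages
that each need little or no training data, because collections of bloom
photographs annotated for aestivation are small.

## Representation

At every point where two adjacent tepal margins cross, exactly one of the
two tepals is in front.  Viewed with the flower interior below the
overlap, the label is **L** when the left tepal is in front and **R** when
the right one is.  Ordering the labels by increasing angle about the
flower centroid (`atan2` with image axes, y down, so increasing angle is
clockwise on screen) gives a circular L/R permutation.  Consecutive label
pairs determine the class of the tepal between them: `(R, L) → I`
(internal — the tepal is above both neighbors), `(L, R) → E` (external —
below both), homogeneous pairs `→ A` (alternating).  Because L→R and R→L
boundaries alternate around the circle, every sequence satisfies
`count(I) == count(E)`; the loader enforces this on catalog entries too.

Whether tepal *i* is paired with overlaps *(i, i+1)* or *(i−1, i)*, and
which of the two mirror-image L/R readings is used, only rotates or flips
the resulting sequence.  Matching is invariant under both (next section),
so these conventions cannot change the final identity — the reason the
package fixes them silently rather than exposing options.

## Matching

Arrangements are circular permutations considered equal under rotation
and reflection (bracelet equivalence).  The cyclic edit distance between
a query and a reference is the minimum unit-cost Levenshtein distance
over all rotations of the query and of its reversal; only the query is
transformed, which suffices to realize every cyclic alignment.  The
linear distance is computed by `edlib`; the test suite cross-checks the
whole construction against an independent dynamic-programming oracle.
The query is matched to the catalog entry at minimum distance; ties set
an `ambiguous` flag, report all co-minimal entries, and resolve
deterministically to the first in catalog order.

The shipped catalog holds 13 reference arrangements for 4–9 tepals (1–3
per count): the whorled type (alternating E/I, plus one A tepal at odd
counts), the spiral type (all A: each tepal covers one neighbor and is
covered by the other), and a one-reversal spiral for 5 and 6 tepals.  It
is a plain TSV meant to be edited; every code path accepts a user
catalog.  `enumerate_arrangements` generates the full conceivable set per
tepal count by brute force over all 2^n depth patterns, for comparing
"observed in nature" against "combinatorially possible".

## Image stages

**Detection.**  The detector is pluggable: any callable mapping an RGB
image to a bounding box (a fine-tuned neural detector in production use).
Inputs for such detectors are letterboxed — scaled to a 256-square with
bilinear interpolation, aspect preserved, content anchored top-left,
black padding — with an exactly invertible coordinate map (anchoring
top-left keeps the map a pure scale).  The built-in fallback needs no
training: it estimates the background color as the border median, marks
pixels whose RGB distance exceeds 40 (of 255), and returns the tight box
of the largest 8-connected salient component.  This exploits the same
property that makes the rest of the pipeline work: the flower contrasts
with its background.

**Segmentation.**  GrabCut-style per-image color modelling: pixels
outside the box are definite background, the box interior initializes
the foreground, and for 5 iterations (default) foreground and background
Gaussian-mixture color models (5 full-covariance components each,
`scikit-learn`) are refit and the interior re-classified by likelihood.
The graph-cut smoothness term of the original formulation is omitted;
on flowers that contrast with their background the color term dominates,
and the final cleanup (largest component, hole filling) removes the
speckle the smoothness term would have suppressed.  An empty foreground
or a box with no exterior raises a segmentation failure — the observable
symptom of foreground/background color collision — rather than silently
returning the whole box.

**Overlap detection.**  Harris corners are computed on the binary mask
(σ = 2 integration, k = 0.04) after Gaussian pre-smoothing (σ = 2); the
pre-smoothing is essential because a rasterized boundary is itself made
of pixel-scale corners.  Peaks above `max(0.005, 0.01 · max response)`
with 10 px non-maximum suppression are snapped to the nearest contour
point when farther than 2 px.  Each candidate then faces the chord rule:
intersect a circle of radius 15 px with the mask contour (with more than
two crossings, the nearest along the contour on each side is used), and
sample the open chord between the two crossings every 0.25 px with
bilinear mask lookups, excluding a 1 px guard at each end.  An
all-background chord marks a concave corner — an overlap point; an
all-foreground chord marks a convex false positive.  Mixed chords are
rejected conservatively, but first the rule is retried at contour points
up to 5 px to either side, because a corner peak that lands slightly off
the wedge apex clips its chord against one margin.  Margin indentations
(notched tepals) can still pass the rule and appear as false positives;
the renderer's `notch_depth` option reproduces this failure mode for
study.  Detection quality is scored by precision/recall/F1 with greedy
one-to-one matching at 10 px tolerance.

## Patches and synthetic supervision

Classification works on 20×20 crops in a canonical orientation: the
chord is rotated horizontal with the flower interior below, so the two
margins form an "X" whose background wedge opens upward.  Original
patches are cropped at overlap points; background pixels are black.

Labeled training data comes from the flower itself.  Circles of radius
10 and 15 px around each overlap cross the contour at four points away
from the overlap wedge; 20×20 crops there contain a single margin and
are classified by the sign of a least-squares line fit to the margin
(|slope| < 0.05 is discarded as ambiguous).  In canonical orientation
the margin rising toward the upper-left belongs to the left tepal, so
compositing a left-up arc *in front of* a right-up arc simulates "left
tepal forward" and is labeled L (the mirrored convention would flip
every label, which matching absorbs).  Compositing pastes the front
patch's own foreground over the back patch after aligning the two
margins vertically so they cross near the patch center — the same depth
cue a real patch shows: the front margin continues across the interior
as a color edge.  Per flower, arcs are pooled across all overlaps,
padded by seeded re-crops with ±3 px uniform integer offsets to a
50-crop quota, balanced to 25 per slope type (seeded subsampling or
further padding), and composed in all 25 × 25 cross-type pairs in both
depth orders: exactly 1,250 synthetic patches, 625 per class.

## Interior-exterior classification

Each flower defines one few-shot task: support = 20 synthetic patches
(10 per class), query = original crops.  Two backends:

**Meta-learned CNN.**  The standard few-shot architecture — four blocks
of 3×3 convolution, batch normalization, ReLU, 2×2 max-pooling, then a
linear 2-way head — implemented in NumPy with hand-written backprop
(im2col convolutions; batch statistics at adaptation time, the usual
transductive choice for episodic training).  Patches are bilinearly
upsampled to the 84×84 input.  Training is first-order model-agnostic
meta-learning: per task, a clone of the initialization takes 5 inner SGD
steps (batch 5, step 0.01) on the support set; the query-set gradient at
the adapted parameters, averaged over the meta-batch, updates the
initialization with Adam (step 0.001).  The first-order approximation
drops the Hessian-vector terms of the exact objective; it is the
standard CPU-scale simplification and empirically matches the full
second-order update closely on episodic benchmarks.  The full-scale
profile (200,000 iterations, meta-batch 20) is configuration-selectable;
the scaled-down profile used by the test suite (500 iterations,
meta-batch 4, 24 px inputs, 16 channels) trains in a couple of CPU
minutes and reaches >0.9 held-out query accuracy on renderer tasks.
Non-finite losses raise a training failure rather than continuing.

**Deterministic baseline.**  A nearest-centroid classifier adapted per
task by fitting class centroids to the support set.  Features: the mean
RGB intensity of each patch quadrant (12 values) and the left/right
asymmetry of interior color-edge energy below and above the patch center
(2 values).  Gradients are taken per channel because two tepal shades
can differ in RGB while matching in gray.  Features are standardized
with support statistics, and the centroid metric is weighted by each
feature's between-class separation so that features on which the
synthetic support does not discriminate (where synthetic and original
patches differ systematically) cannot dominate.  Confidence is a softmax
over negative distances; exact ties break to L.  The baseline needs no
training, which makes the full pipeline runnable and testable end to end
without a GPU-scale training budget.

## Synthetic flowers

The renderer emulates the data regime the pipeline targets: one flower
per image, contrasting background, 4–9 tepals (3 supported), overlaps
only between angular neighbors.  Tepals are rotated ellipses in an
annulus around the canvas center (inner tips at 22 % of the flower
radius; tangential half-width 1.45 · d · sin(π/n), jittered a few percent
per tepal), and a central disc — the receptacle — covers the region where
the inner boundary crossings would otherwise notch the silhouette.  The
geometry is validated per render (non-adjacent pairs disjoint, each
adjacent pair crossing exactly twice, a disc radius strictly between the
inner and outer crossings, disc boundary covered by the tepal union);
violations raise a renderer-infeasible error instead of producing wrong
ground truth.

Depth is prescribed per adjacent pair, not by a global z-order: a cyclic
pattern in which every tepal covers its clockwise neighbor (the all-A
spiral) admits no total ordering, but repainting each pairwise
intersection with its front tepal's fill is exact when only neighbors
intersect.  Optional per-tepal shade variation (default on, ±40 per
channel around the base color, pairwise-distinct) provides the color
edge the classifiers key on.  Ground truth per render: the mask, the
box, each outer crossing with its L/R label, and the arrangement
obtained by ordering those labels by angle — the same code path the
pipeline uses, closing the loop for self-consistency tests.

What the renderer does **not** emulate: lighting and shading, tepal
texture and veins, fold shadows, specular highlights, defocus, multiple
flowers, and margins that are anything but smooth ellipses (except the
optional notch).  Passing tests on renders therefore demonstrates the
geometry and logic of the method — not photograph-level robustness; on
real images the classification stage in particular degrades with
lighting, which is why the correction workflow exists.

## Correction workflow and evaluation

Every pipeline run emits a JSON annotation record (box, points with
labels/confidences/corrected flags, sequence, match, provenance with a
config digest; unknown fields round-trip).  Corrections are structured
edits — add a point with a label, remove a point, flip a label —
validated against the record (references must land within 3 px of an
existing point) and followed by recomputation of ordering, conversion
and matching.  Replacing all detected points by the true ones always
yields the true arrangement; an interactive UI could sit directly on
this record format.

`evaluate` summarizes record/truth pairs: mean detection IoU, mean
segmentation IoU, pooled overlap precision/recall/F1 (10 px), interior-
exterior accuracy over matched points, arrangement accuracy, and the
integrated estimate `(p_detect · p_classify)^n` at the mean overlap
count — the closed-form expectation that every one of n independent
per-overlap decisions succeeds.  The pipeline's observed arrangement
accuracy typically exceeds this estimate because the edit-distance
matcher absorbs some single-point errors.

## Problem sizes and numerical choices

The test suite renders at 420×280 (geometry is scale-free; the chord
radius and patch size are absolute pixels, chosen for 1000×662 images,
and still well-behaved at this scale).  The end-to-end check uses 50
class-balanced renders; the meta-learning check trains three seeds at
the scaled-down profile and takes the median.  Determinism: every
stochastic component takes an explicit seed (`numpy.random.default_rng`);
renders are bit-identical per spec, patch sets and training runs
reproduce exactly on one machine.  Ties are resolved deterministically
throughout (catalog order for matches, L for centroid ties, angle then
radius then x for overlap ordering).  Degenerate inputs raise typed
errors (`tepals.errors`) rather than returning best guesses.

Known limitations: no learning-based overlap detector (concavity is a
rule, so unusual margins defeat it); the baseline classifier's features
are tuned to color cues and would not survive grayscale images; the
first-order meta-update is an approximation; the renderer's realism
limits are listed above; multi-flower images are out of scope.
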