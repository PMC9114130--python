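# Methods

`colonymorph` categorizes the development of microbial colony morphology
from time-lapse photographs.  The pipeline has five stages: segmentation,
texture scoring, dimensionality reduction, trajectory assembly, and
representative clustering.  This note records the model behind each stage,
the tunable parameters and their defaults, the numerical choices, what the
synthetic-data generator does and does not emulate, and the known
limitations.

## Segmentation (`preprocess`)

A photograph contains one colony on a noisy background that may include
plate edges.  Extraction proceeds in three steps:

1. **Canny edge detection** (`skimage.feature.canny`) marks object
   boundaries.  Defaults: Gaussian `sigma = 2.0` px; hysteresis thresholds
   as the 60th/90th *quantiles of the gradient magnitude* (quantile
   thresholds adapt to exposure differences between frames).
2. **Circular Hough transform** (`skimage.transform.hough_circle`) over
   radii spanning 10–45% of the smaller image dimension locates the colony
   boundary.  The normalized accumulator value of a candidate circle is the
   fraction of its perimeter supported by edge pixels.  Selection rule: any
   circle with support ≥ `hough_support_floor` (default 0.5) is treated as a
   real object and the **largest radius** among them wins — the colony
   boundary is the outermost circular structure, and strong surface texture
   (concentric ridges) produces crisp *inner* rings that would otherwise
   capture the peak.  If nothing reaches the floor, candidates within
   `rel_threshold` (0.9) of the peak are used.  Remaining ties go to the
   higher accumulator value, then the smaller (row, column) centre.  For
   speed the transform runs on a 2× subsampled copy of the image
   (`hough_downscale`); the circle is scaled back before masking.  The
   boundary is a large, high-contrast structure, so subsampling costs at
   most ~2 px of radius accuracy.
3. **Foreground hull.**  Pixels outside the circle are masked.  An Otsu
   threshold computed over the *whole image* separates colony from
   background; thresholding only the circle interior would split the
   colony's own texture (bright folds vs dark troughs) and clip its
   boundary, because a tight circle contains almost no background.  The
   colony mask is the convex hull of the in-circle foreground
   (`convex_hull_image` with `offset_coordinates=False`, which is exactly
   idempotent on rasterized masks).  A frame whose hull covers less than
   30% of its circle's area is rejected — the circle landed on background
   clutter — and the frame is dropped; gaps are filled later in feature
   space, never at image level.

The masked colony is cropped to its bounding box, padded to a square (fill:
5th percentile of the masked background, i.e. a dark robust fill that adds
no spurious edges), and resized with anti-aliased bilinear interpolation to
a standard 100 × 100 frame.  Padding before resizing preserves the colony's
aspect ratio.

## Texture scoring (`texture_features`)

Each standardized frame is scored with the rotation-invariant uniform
**local binary pattern** (LBP).  Every pixel is compared with
`n_neighbors = 8` points on a circle of `radius_px = 1.0`; a neighbour at
least as bright as the centre contributes bit 1.  Circular bit patterns
with at most two 0↔1 transitions are *uniform* and take their number of
set bits as the category (0–8); all 198 remaining patterns share the
catch-all category 9.  Enumerating all 256 patterns yields 58 uniform ones
— the categories partition texture into bright spots, dark spots, edges,
corners and a mixed class.  The relative frequencies of the 10 categories
over the (mask-restricted) frame form the frame's point in **LBP space**;
all spatial arrangement is integrated out, which is what makes the score
robust to the colony's outward growth.

**Sampling convention.**  Neighbours are sampled at the *nearest pixel* to
each circle position (for radius 1, the classic 3×3 ring).  This choice
makes two invariances exact rather than approximate, and both are asserted
exactly in the test suite:

* 90°-rotation invariance: the offset set is closed under quarter turns,
  so rotating the image permutes each pixel's neighbour ring.
* Monotone-remap invariance: only raw pixel comparisons enter the code, so
  any strictly increasing intensity transform (gamma, exposure, contrast)
  leaves every code unchanged.

Bilinear circle sampling (the convention of
`skimage.feature.local_binary_pattern`, available as
`sampling="bilinear"` and cross-checked against scikit-image bit for bit)
breaks the second invariance: interpolation does not commute with
nonlinear remaps, and on a random 100×100 frame ~13% of codes change under
squaring.  A pixel is counted in the histogram iff its centre lies in the
colony mask and its full neighbourhood is in bounds; neighbours may sample
masked background (boundary pixels are a vanishing fraction at 100×100).

**PCA.**  The histograms of every frame of every colony are pooled and
reduced by mean-centred SVD (`numpy.linalg.svd`).  Three modes are
retained by default (`n_modes = 3`); on both the synthetic ensembles and
the published data style of histograms they capture the large majority of
variance.  The sign of each mode is fixed so its largest-magnitude entry
is positive, making the fit deterministic.  Rank-deficient inputs return
fewer modes with a warning.

## Trajectories (`trajectories`)

Frames arrive at irregular times, so per-frame 3-vectors are binned onto a
shared grid (`bin_hours = 1.0`; frames within a bin are averaged).  The
grid ends at the **median** of the colonies' last observation times (lower
median for even counts; rounded down to a bin boundary) — the median is
robust to failed-growth experiments that end early.  Interior gaps are
filled by linear interpolation per coordinate; bins after a colony's last
observation hold its final value constant (**saturation extrapolation** —
growth is assumed to have plateaued); bins before the first observation
hold the first value (the symmetric rule; extrapolating a trend from a
single point would be less stable).  Observed/filled provenance flags are
kept on every bin.

The distance between two colonies is the **mean over grid bins of the
Euclidean distance** between their 3-D feature points.  The mean (rather
than the sum, available via `distance_mode="sum"`) is invariant to the
grid length, so distances are comparable across re-analyses with different
final times.  Being a mean of norms of differences, it satisfies the
metric axioms, which the tests verify on random triples.

## Representative clustering (`prototype_clustering`)

Hierarchical agglomerative clustering under **minimax linkage**:

    d(G, H) = min_{c ∈ G∪H} max_{x ∈ G∪H} dist(c, x)

the smallest radius of a ball centred on a *member* that covers the merged
cluster.  The minimising centre is the cluster's **prototype** — an actual
colony whose image series best represents the cluster, which is the point
of the construction for image data.  Minimax linkage yields monotone merge
heights (no dendrogram inversions), so horizontal cuts are interpretable.
Ties are fixed for bit-reproducibility: merge pairs by smallest node-index
pair, prototypes by smallest leaf index.  The implementation recomputes
each new cluster's linkage to the others vectorised over the distance
matrix; correctness is defined by a brute-force oracle that the tests run
on 100 random instances.  It comfortably handles hundreds of colonies;
for ensembles in the thousands the per-merge union scan is the bottleneck
and a candidate-radius cache would be the next optimisation.

**Cut selection.**  Cuts are taken at a height or a cluster count k; k is
chosen by maximising the **Calinski–Harabasz index**

    CH(k) = [B/(k−1)] / [W/(n−k)]

with B and W the between/within-cluster sums of squares of the *flattened
trajectory vectors* (grid length × 3 per colony).  CH needs centroids,
which exist in trajectory space but not in a general metric space; using
the flattened trajectories keeps the score consistent with the distance
(the squared trajectory distance is a scaled quadratic in the same
vectors).  A partition with W = 0 returns a large finite sentinel (1e300),
ranking above any real score deterministically.

The scan range defaults to `2 ≤ k ≤ min(50, ⌈√n⌉)`.  CH is an F-ratio-like
statistic: it is comparable across k only while clusters keep several
members each, and as k → n the within-scatter collapses toward zero, so CH
diverges for *any* data and an unbounded scan always selects near-singleton
partitions.  The √n ceiling is the usual rule of thumb; the cap of 50
keeps scans of very large ensembles tractable (for an ensemble of
thousands the two coincide).  The range is user-overridable, and any
subtree can also be re-cut at an explicit height.

## Synthetic generator (`synthetic_colony`)

The generator emulates exactly the statistical structure the pipeline
assumes and nothing more: a roughly circular bright colony (disk intensity
0.7, background 0.25× that, Gaussian pixel noise `noise_sd = 0.02`) that
grows along a symmetric logistic from 30 px to 90 px over 72 h (midpoint
at half the duration; steepness fixed so ~99% of the span falls inside the
duration), photographed at jittered intervals (median 23 min by default,
matching the cadence of the real acquisition rig; ±30% uniform jitter;
10% frame dropout) on a 256×256 canvas, so the resize stage is exercised.
Four texture classes with frozen presets: *smooth* (amplitude 0), *ridged*
(concentric rings, amplitude 0.35, 0.08 cycles/px), *lumpy* (Gaussian
bumps, amplitude 0.5, σ = 5 px) and *cratered* (a negated bump field with
finer grain, σ ≈ 2.8 px — crater fields differ from bump fields in feature
scale as well as sign, and a sign flip alone would leave the two classes
much closer to each other than to anything else).
Bump positions are fixed in colony-relative coordinates per colony, so the
texture grows coherently outward; texture amplitude ramps in linearly with
radius, so young colonies of all classes look alike.  Ensemble generation
adds ±10% per-replicate uniform jitter to growth and texture parameters
(`REPLICATE_CV = 0.1`): replicate colonies of one strain are biologically
variable, not clones, and without this the smooth class degenerates into
near-duplicate trajectories no real ensemble shows.  All randomness is
seeded per (master seed, colony, frame), so dropout does not shift
textures and every output is a pure function of its seeds.

What the generator does **not** emulate: real fold geometry (its textures
are stationary fields, not mechanically buckled surfaces), illumination
gradients, camera vignetting or focus drift, colony translation, and
neighbouring colonies in frame.  Tests passing on synthetic ensembles
therefore demonstrate the pipeline's *mechanics* — segmentation accuracy,
invariances, metric structure, recovery of separable texture classes — not
performance on any particular real dataset.

**Reference study.**  `pipeline.four_class_study(seed)` freezes the
package's reference conditions: 12 replicates of each of the four classes,
72 h of growth, photographed at a 2 h median cadence (a reduced problem
size — ~35 frames per colony instead of the rig's ~190 — chosen so the
full study runs in minutes on one core; the cadence still leaves most
hourly bins observed).  The acceptance script and the end-to-end test both
run this study and require the CH-selected cut to recover the four classes
exactly, with four prototypes from four distinct classes.

## Degenerate inputs and numerical conventions

* Constant images: no edges (not an error); LBP histogram is a point mass
  on category 8 (all neighbours ≥ centre).
* Empty edge map → circle-detection error advising parameter changes; a
  segmentation failure drops the frame, never the colony.
* Duplicate (root name, timestamp) files: lexicographically first wins,
  with a warning.
* Condensed distance storage follows the `scipy.spatial.distance.squareform`
  convention; indices in the distances CSV are 0-based positions in the
  sorted id list.
* The iteration field of a root name is zero-padded to three digits on
  output; parsing accepts any width.
* CSV stage outputs are the interface between pipeline stages: after
  writing a stage's CSV the pipeline re-reads it, so resumed runs are
  byte-identical to fresh ones.

## Known limitations

* The LBP radius the original analysis used is not recorded anywhere;
  radius 1 is the package default and other radii are configurable but
  untested against published coordinates.
* Segmentation assumes one colony per frame; scenes with several colonies
  or heavy plate-edge content need cropping first.
* The minimax implementation targets ensembles up to a few thousand
  colonies; beyond that, expect quadratic-plus growth in merge cost.
* CH-based cut selection inherits CH's bias toward splitting elongated or
  heteroscedastic clusters; the dendrogram itself (and explicit-height
  cuts) remain available when the automatic k is not convincing.
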