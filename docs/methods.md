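# Methods

This note documents the models, conventions and numerical choices behind
`nucannotate`, in the order the pipeline applies them, followed by the
synthetic-data model and the evaluation conventions.

## Scope and assumptions

The pipeline assumes 2-D single-channel fluorescence images in which one
object class — stained cell nuclei — is bright on a dark background, is
the dominant object class by count, and has low variance in projected
area. Everything downstream follows from those three assumptions: a
single global threshold separates foreground from background, connected
bright regions are objects, and the area distribution identifies which
objects are single nuclei. The pipeline does not attempt to annotate
every nucleus; it trades completeness (typically ~60–70 % of nuclei
captured on crowded fields) for per-object label quality, which is the
right trade for producing training data.

## Pre-processing

Pixel-value conversion is monotone rescaling only. The default is
percentile scaling — clip at the 1st and 99th intensity percentiles,
then map linearly to the 8-bit range — because 16-bit widefield data
routinely contains hot pixels that would compress a min-max mapping.
Min-max and no-op modes are available; a constant image maps to all
zeros by convention. Thresholding operates on the converted image by
default, but nothing in the Otsu implementation requires 8-bit input.

Tiling (for networks with fixed input geometry) cuts exact
`tile_size`-squares stepping by `tile_size − overlap`; the final row and
column of tiles are anchored to the image edge rather than padded, so
tiles never contain fabricated pixels. Only an image smaller than one
tile is zero-padded (with a warning).

## Otsu thresholding

The threshold minimizes the intra-class variance
`σ²_W(t) = W₀(t)σ₀²(t) + W₁(t)σ₁²(t)` over candidate splits of a
256-bin histogram (256 bins regardless of bit depth; 16-bit data is
binned). Implementation details that matter:

* Per-bin statistics are exact moments (count, sum, sum of squares of
  the actual pixel values), not bin-center approximations. On 8-bit
  data the value-to-bin mapping is injective, so the scan is numerically
  identical to an exhaustive per-value search — this is tested against
  an independent brute-force oracle.
* Candidate splits that leave either class empty are skipped (the
  criterion is undefined there), not scored as zero.
* Ties are broken toward the smallest threshold, which favours a larger
  foreground; spurious small objects this admits are removed later by
  the area filter.
* Foreground is strictly `value > t*`; the returned `t*` is the largest
  pixel value of class 0, so the comparison reproduces the optimal
  split exactly for any dtype.
* A constant image raises a degenerate-input error rather than
  returning an arbitrary threshold.

Minimizing within-class variance is equivalent to maximizing
between-class variance; the test suite checks split-level agreement
with scikit-image's implementation of the latter formulation.

## Watershed labelling

Instance labels come from flooding the negative Euclidean distance
transform of the binary mask, restricted to the foreground, from seed
markers. 8-connectivity is used throughout (components, flooding), the
natural choice for roundish objects.

The marker rule is the one genuinely open design decision. By default
(`min_peak_distance=None`) each connected foreground component receives
exactly one marker at its distance-transform maximum: an object
separated from the background gets one label, and merged objects —
touching nuclei, clusters — are never split. This is deliberate and
load-bearing for the stage that follows: merged objects must survive as
single large objects so the area filter can remove them, which is what
makes the kept set almost purely single nuclei. Splitting merged nuclei
at distance-transform ridges is available by passing a pixel
`min_peak_distance` (peaks are then suppressed pairwise within each
component, and any component where peak detection finds nothing still
receives its maximum, so the output always partitions the foreground
with exactly one label per marker). Split fragments of touching nuclei
have near-single areas and would pass the area band, polluting the kept
set — hence splitting is opt-in, for users who post-process differently.

## Pixel-area filtering

The median area `m` is computed once, over all objects pooled across
the whole run (not per image — pooling is what the dominant-class
argument licenses, and it stabilizes small images). An object is kept
iff its area lies in `[(1−f)·m, (1+f)·m]` with `f = 0.5` by default;
"deviating by more than 50 % of the median" is the reading under which
both the too-large exclusions (clusters, merged nuclei) and the
too-small ones (debris, artefacts) make sense. Bounds are inclusive,
the median of an even count is the mean of the two central values, and
the filter is a single pass — the band is not re-estimated after
exclusion. Kept labels are renumbered sequentially in their original
order.

## Composition and background noise

The training image keeps the (preprocessed) pixel values of kept
objects and zeroes everything else, so mask labels and nonzero image
support correspond exactly. Because a perfectly homogeneous black
background is an artificial cue a network will exploit, Gaussian noise
(mean 0, sd 3 on the 8-bit scale) is added to background pixels only,
clipped to the bit-depth range; on a zero background the negative half
clips away, i.e. the effective distribution is half-truncated, which
the tests check against a Monte-Carlo simulation of the same rule.
Noise distribution (gaussian/uniform), amplitude and scope
(background-only vs whole image) are configurable; per-image seeds are
derived as `seed + image_index` so runs are reproducible but images get
distinct noise.

## Evaluation conventions

* IoU is exact pixel-count intersection over union per instance pair;
  the pair table is symmetric under swapping the two maps.
* Matching at threshold `t` is greedy over pairs with IoU ≥ t in
  descending-IoU order, ties broken by (gt id, pred id). At `t ≥ 0.5`
  any pixel supports at most one pair above threshold, so the greedy
  matching is optimal; the tests verify equality with an exhaustive
  assignment search on small instances.
* TP + FN = number of ground-truth objects and TP + FP = number of
  predictions, at every threshold. Object-level true negatives are
  undefined and carried as 0; no formula uses them.
* A metric whose denominator is zero is defined as 0.
* Mean IoU is reported in two conventions, because they answer
  different questions: over matched pairs only (how good are the
  annotations that were made) and over all ground-truth objects with
  unmatched ones contributing 0 (how much of the truth was annotated).
  The restricted evaluation mode additionally drops ground-truth
  objects whose best-overlap automatic object was excluded by the area
  filter — those were knowingly not annotated; ground truth with no
  overlapping automatic object at all was *missed*, and stays in.
* All metrics are invariant under label permutation of either map.

## Synthetic data model

The generator renders what the pipeline's assumptions describe: bright,
roughly elliptical nuclei on a dark noisy background, in four object
classes — isolated singles (area-preserving ellipse axes `r√q`, `r/√q`
with axis ratio `q`), touching pairs (two circles, centers at 0.8× the
sum of their radii: one connected component, two labels, the overlap
strip owned by the first-placed member), clusters (one central circle
with satellites overlapping it the same way: one large blob), and
debris (discs of radius 1–3 px, below half the median single-nucleus
area by construction). Placement is rejection sampling with a 3-px
clearance between groups and a 1000-attempt budget; requests whose
total object area exceeds half the image are rejected up front.
Intensities are one mean draw per instance plus per-pixel Gaussian
jitter, over a flat noisy background, clipped to the bit-depth range.
The whole field is a pure function of the spec and its seed.

Default study conditions, chosen once: 512×512 8-bit fields with 24
singles, 4 touching pairs, one 4-nucleus cluster and 6 debris — about
two thirds of the nuclei are capturable singles, the regime crowded
fluorescence fields present; nucleus radius 12 ± 2 px; foreground
180 ± 20, background 10, background noise sd 3 (≤ 5 % of the foreground
mean, so classes are separable by a global threshold). The cluster size
of 4 keeps the cluster blob's area above the filter's upper bound with
margin even for small-radius draws.

What the generator does *not* emulate — and what passing tests on it
therefore cannot show: uneven illumination, out-of-focus light and
other spatially structured background; intensity gradients within a
nucleus; non-elliptical or lobed nuclear shapes; mitotic figures;
partial nuclei at image borders (objects are placed fully inside); shot
noise. Results on real widefield data will be worse than on fixtures,
primarily through the binarization step; the pipeline's structural
guarantees (partition, filter band, matching identities) are
data-independent.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so a
full run completes in well under a minute on one CPU: 160²–384² fixture
fields with 5–23 objects for property sweeps (100 seeded fields for the
watershed partition property, 20 replicates for filter purity, 50
random 256² images for the Otsu oracle), and a five-image 512² dataset
with 180 nuclei for the end-to-end quantities. The annotation-
performance ratios are recomputed from the reference bookkeeping of a
manually annotated 6409-nucleus comparison dataset (4339 captured,
300 s vs 54 000 s).

## Known limitations

* One global threshold: fields with strong illumination gradients need
  flat-field correction upstream; no local/adaptive thresholding.
* The filter identifies *one* dominant class by area; datasets with a
  broad or multimodal single-nucleus area distribution (e.g. mixed cell
  lines, heavy mitosis) violate its premise.
* Touching nuclei are excluded, not annotated — by design; a network
  trained on the output will under-segment dense clumps unless its own
  inductive bias (e.g. star-convexity) compensates.
* Wall-clock timings in the run report are hardware-dependent and are
  reported for bookkeeping only.
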