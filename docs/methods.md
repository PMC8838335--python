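# Methods

## Data model and coordinate conventions

Boxes are continuous corner-form rectangles `(x_min, y_min, x_max, y_max)`
with origin at the image's top-left corner and no pixel-centre offset;
COCO's `[x, y, w, h]` interchange is converted on read and restored on
write, which is an exact bijection on rational coordinates.  Boxes may be
expressed in pixels or normalized to the unit square; fusion always
operates on normalized coordinates (weights and IoU are scale-free, but a
single convention avoids mixed-unit accidents).  Detector boxes that
overshoot the image border are clipped at normalization time with a logged
warning rather than rejected, since real detector outputs routinely
overshoot by a few pixels.  A category id is carried everywhere even
though the motivating application has a single class (fracture):
clustering and matching are always per image *and* per category.

## Weighted boxes fusion

Per image and category:

1. boxes with raw confidence below `skip_box_thr` (default 0.3) are
   dropped;
2. each surviving box gets an effective confidence `c = s · w̃_m`, where
   the model weights are normalized to mean one, `w̃ = w·N/Σw` (`N` =
   number of models).  Normalizing makes the output exactly invariant to
   rescaling all weights by a constant — weights only matter relatively —
   while reproducing the standard WBF scores when all weights are equal;
3. boxes are visited in descending effective confidence (ties broken by
   model index, then original detection order).  A box joins the first
   existing cluster whose *current fused box* overlaps it with
   IoU > `iou_thr` (default 0.5, strict inequality); otherwise it opens a
   new cluster.  The fused box is recomputed after every insertion, so a
   cluster's representative drifts toward its members' consensus;
4. fused coordinates are the effective-confidence-weighted mean of the
   members; the fused confidence is the mean effective confidence times a
   support factor `min(T, N)/N` (`T` = member count; modes `T/N` and
   `none` are selectable).  With unequal weights the product can
   marginally exceed 1 and is clipped — a deliberate trade for the exact
   weight-scale invariance above;
5. fused boxes are sorted by confidence per image and truncated to
   `limit_boxes` (default 6000, effectively no-op at desk scale).

Singleton clusters return the member's coordinates verbatim instead of a
weighted mean of one element, so a single-model, single-box fusion is an
exact identity rather than identity-up-to-rounding.

`fuse_brute_force` is an independently written O(n²) twin — no sorting
(repeated full scans select the next box), cluster statistics recomputed
from scratch at every insertion — whose output must be byte-identical to
`fuse`; the test suite checks this on 100 random instances.  When `numba`
is importable, the clustering inner loop of `fuse` runs as a JIT kernel
whose arithmetic mirrors the Python path operation-for-operation; the
brute-force twin stays pure Python, so the equality suite genuinely
exercises the kernel.  Without numba a pure-Python path with the same
semantics is used.

## Evaluation

Matching is the standard greedy protocol: per image and category,
detections in descending confidence are matched to the unmatched ground
truth of highest IoU provided IoU ≥ τ (default 0.5).  Score ties are
broken by input order; equal-IoU ground truths by index.  Images without
ground truth contribute false positives only.

*AP50* pools detections across images, builds the precision-recall curve,
makes the precision envelope monotone and integrates — by the COCO
101-recall-point rule by default, or as the exact area of the staircase
curve (`all_point`).  With several categories, AP is the mean over
categories that have ground truth.  *AR* is the mean recall over the IoU
grid 0.50:0.05:0.95 with at most `max_dets_per_image` (default 100)
highest-scoring detections per image — the discrete equivalent of twice
the area under the recall-IoU curve on [0.5, 1.0].

The *LRP* error at a confidence threshold combines a localization term
over true positives, `Σ (1−IoU)/(1−τ) / N_TP`, with `1−precision` and
`1−recall`; the total is `[Σ(1−IoU)/(1−τ) + N_FP + N_FN] / (N_TP + N_FP +
N_FN)`.  Empty-denominator conventions: precision (recall) is 1 with no
detections (no ground truth); LRP of an empty scene is 0; no detections
against non-empty ground truth give LRP 1.  *oLRP* minimizes LRP over the
candidate thresholds (every distinct detection score plus 0 and 1), with
ties resolved toward the larger threshold (fewer detections kept).
Because greedy matching of the detections above any threshold is a prefix
of the full greedy run, one matching pass plus a cumulative sweep
suffices; the minimum-property test cross-checks the sweep against
independent fixed-threshold evaluations.

## Ensemble search

For a pool of `m` models the search space is every subset of size
`k = 2..m` crossed with every integer weight vector in `{1..k}^k`,
enumerated deterministically (subsets lexicographic by member index,
weights odometer-style): `Σ_k C(m,k)·k^k` configurations — 388 for
`m = 4`, 4715 for `m = 5`.  Each configuration is fused on the validation
split and scored by the criterion (AP50, AR, or negated oLRP); ties go to
the first configuration in enumeration order, so searches are exactly
reproducible.  A seeded random-subsample mode bounds the cost for larger
pools.  The winning configuration is meant to be applied unchanged to a
held-out test split; the API takes separate dataset arguments to keep
that discipline.

The five first-level ensembles are built from criterion-defined pools —
all single-stage models, all two-stage models, top-k by AP50, top-k by
AR, top-k by lowest LRP-optimal threshold — searched with max-AP50 for
the first three pools (AP50 being the headline metric for the
architecture pools, whose selection metric is otherwise unspecified),
max-AR for the AR pool and min-oLRP for the LRP pool.  Pools with fewer
than two members are skipped with a warning.  `PUBLISHED_WFD_CONFIGS`
ships the published wrist-fracture ensembles (members and weights,
including the combo's `(4, 4, 3, 5, 5)`) as a reference fixture; the
clinical detections required to recompute them are not public.

### The second level (combo)

The combo treats the five first-level fused outputs as a new pool and
searches it with the max-AP50 criterion.  Its default fusion parameters
differ in one place: the skip-box threshold is 0.  The 0.3 threshold has
already been applied to raw detector confidences at the first level, and
first-level fused confidences live on a compressed scale — a box
supported by `T` of `N` models carries a `min(T, N)/N` factor — so
re-applying a raw-score threshold at the second level would silently
discard the recall tail that every first-level output deliberately
retains (empirically this costs the combo 1-5 AP50 points and makes it
*worse* than its best input).  With skip 0, configurations dominated by
the best member keep that member's full recall, and whenever two
first-level searches select the same configuration the combo can
reproduce their output exactly; the searched combo therefore tracks the
best first level from above.

## Synthetic benchmark

`generate_scenes` draws, per image, 1 or 2 ground-truth boxes (95%/5%,
matching ~1.05 boxes per image, i.e. 569 lesions in 542 images) with
sides uniform in 48-160 px inside 800×800 images.  `split` partitions
images 80/10/10 by rounding each fraction to the nearest integer and
fixing the largest partition (542 → 434/54/54); an optional patient-tag
mapping keeps all images of one patient in the same partition.

`simulate_detector` detects each ground-truth box with probability
`p_detect`, applies corner-wise Gaussian jitter (truncated so boxes stay
valid and inside the image) and draws a confidence from a Beta
distribution; false positives are a per-image Poisson process with
uniformly placed boxes and their own Beta confidences.  Two archetypes
are calibrated to the characteristic threshold-versus-box-count profiles
of real detector families: the single-stage archetype emits many boxes
whose count collapses as the score threshold rises (low-mean Beta false
positives, ~6 per image); the two-stage archetype emits few, confident
boxes whose count declines gently (high-mean true-positive scores, <1
false positive per image).  Detection probabilities default to 0.95:
real detectors almost always emit *some* box near a lesion — quality
shows up as localization error, confidence and false positives, not as
absent boxes.

`box_hardness` adds the one correlation structure that matters for
ensembling: a per-lesion difficulty in [0, 1] (Beta(0.6, 1.8)) shared by
all detectors, scaling each model's jitter by `(0.5 + 2h)` and its
detection probability by `(1 − 0.3h)`.  Subtle lesions are thus poorly
localized or missed by *every* model at once, as in real ensembles.
Confidences are left untouched — in these archetypes the low-score mass
is false positives, not under-confident true positives.

What the simulator does **not** emulate: image content (no pixels are
rendered), anatomically structured false positives (real FPs cluster on
confusable structures; simulated ones are uniform, which makes them
easier to out-vote than in practice), inter-model score-calibration
differences beyond the two archetype families, and duplicate detections
of one lesion by one model.  Passing tests therefore demonstrate the
correctness and internal consistency of fusion, search and metrics under
controlled conditions — not clinical performance.

`plant_ensemble_optimum` builds recovery scenarios: three planted
detectors with complementary blind spots (the ground truth is partitioned
into three shares; detector *i* misses share *i* entirely and finds the
rest at 0.98 with tight boxes and ~0.1 FP/image) plus noise-dominated
models.  Fusing the planted subset beats any single member by
construction, and the exhaustive search is expected to recover it.

## Preprocessing

Background polarity is decided by a binary k-means on the 256-bin
intensity histogram (weighted Lloyd iterations initialized at fixed
centroids 64 and 192 — deterministic and equivalent to clustering the raw
pixels at bounded cost); the majority cluster is the background, and the
image is inverted iff that cluster is the brighter one.  Constant images
are degenerate and default to "dark" with a warning.  CLAHE is
implemented with the OpenCV clip-limit convention (the limit is a
multiple of the uniform histogram height — the convention in which a clip
limit of 7.0 is meaningful; the scikit-image implementation uses an
incompatible normalized limit): the image is padded by edge reflection to
a multiple of the tile size, per-tile 256-bin histograms are clipped with
the excess redistributed uniformly in one pass, and each pixel bilinearly
interpolates the four nearest tile mappings.  The model input is a
bilinear resize to 800×800 replicated to three identical channels; a
same-size resize is an exact identity.  DICOM pixel data is windowed to 8
bits by min-max scaling — a documented placeholder, since clinical
conversions may use modality window centre/width instead.  The manual
region-of-interest crop used in curating wrist images is out of scope; an
optional crop rectangle argument stands in for it.

## Problem sizes and numerical choices

The test suite's recovery experiment uses 20 seeds × 100 images with a
4-model pool (388 configurations per seed); the combo experiment uses 20
seeds × 100 images with six simulated detectors, 3-member pools and the
full 4715-configuration combo search.  Oracle-equivalence suites run 100
random instances of up to 4 models × 8 boxes.  Tolerances: exact equality
for fusion-oracle agreement and determinism checks; `pytest.approx`
defaults (relative 1e-6) for hand-computed metric values; expectation
checks on the generator use 3-4 standard errors across 20 seeds.  All
generators take explicit integer seeds and are bit-reproducible.
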