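# Methods

`endoquant` counts and phenotypes intracellular endosymbionts (the obligate
aphid symbiont *Buchnera aphidicola* is the motivating case) in
single-channel confocal micrographs of host bacteriocytes. This note
documents the models, conventions, parameters, and design choices, and what
the synthetic-data tests do and do not establish.

## Geometry conventions

All coordinates are 0-based `(row, col)`; boxes and tile windows are
half-open `[min, max)`. An object is a `Mask`: a tight boolean raster plus
the global offset of its origin, so translation during stitching is pure
offset arithmetic. Polygon annotations (labelme `(x, y)` vertex convention,
x along columns) are rasterized by the **pixel-center-inside** rule: pixel
`(r, c)` belongs to the polygon iff the point `(c + 0.5, r + 0.5)` lies
strictly in the interior. Boundary-grazing centers are resolved by that
rule alone. The rasterized area converges to the shoelace polygon area as
shapes grow (relative error < 2 % above ~100 px extents), which the test
suite checks. IoU and union areas are computed on global pixel sets.

Result files store each final detection as its **exact pixel-edge boundary
polygon** (union of unit squares), so writing and re-reading a result file
reproduces every mask's pixel set bit-exactly. This is what makes the batch
curation path (removals + hand-drawn additions in a JSON edit file, standing
in for an interactive review GUI) lossless and reversible.

## Tiling and stitching

Fixed-size detectors see 512 x 512 px tiles; input images must be at least
512 px per side, and lossy formats are refused at the reader.

* **Training dialect** — non-overlapping 512-px grid from the image origin;
  right/bottom remainders of non-multiple images are discarded. Annotations
  are clipped per tile; fragments under 10 px are dropped as unlabelable
  slivers (the clipping policy for border-straddling objects is otherwise
  unconstrained, and this is the least surprising choice).
* **Inference dialect** — overlapping windows with an 85-px overlap, i.e.
  stride 427, the final window per axis clamped to end at the image edge
  (which enlarges the last overlap). An 85-px overlap and a 5 x 5 layout on
  2,048-px images are only jointly consistent with this clamping; the rule
  generalizes to any side >= 512 (1,024 px -> 3 x 3).

After per-tile detection, stitching translates detections to global
coordinates without dropping anything. Two cleanup passes follow, in this
order:

1. **Median size filter.** With `m` the median mask area over the whole
   stitched image, detections with area `< 0.10 m` or `> 5 m` are removed
   as false positives. The inequalities are strict: areas exactly at either
   bound survive. The median is the conventional even-count midpoint.
2. **Overlap deduplication.** Within the tile-overlap strips — the only
   place tiling can present one object twice — any pair of detections with
   mask IoU > 0.5 loses one member, chosen by a seeded coin flip.
   Candidates are processed in deterministic (centroid row, col) order, so
   chains of more than two mutually overlapping detections resolve
   reproducibly; for a fixed seed the survivor set is identical across
   runs, and no surviving candidate pair exceeds the IoU bound. Detections
   outside the overlap strips are never touched, following the stated
   motivation of the rule (double counting in the overlap areas); a flag
   can widen the pass to the whole image.

## Detectors

Detection is a plugin contract: any callable `(tile, config) -> [Detection]`
works. Scores live in `[0.01, 1]` (0.01 = no resemblance to the target
morphology). The orchestrator pads sub-512 edge tiles with zeros, drops
candidates below the 0.5 head-score threshold, and truncates to the 1,000
highest-scoring proposals per tile.

* **Neural configuration schema.** The validated Mask R-CNN configuration
  is recorded as data: ResNet50 residual blocks 2–5 feeding an FPN with
  16/32/64/128-resolution maps, square anchors of 32/64/128/128 px (the
  16-px and 256-px defaults are dropped as too small/large for ~1-um
  toroids; the duplicated 128-px entry for the two coarsest maps is
  recorded as such), up to 1,000 proposals per tile, a 4-layer x 256-channel
  mask head, a 2-layer x 1,024-unit box head, and a 40,000-iteration SGD
  schedule with warmup + cosine decay. Training itself and shipped weights
  are out of scope; an external detectron2 adapter can sit behind the same
  contract.
* **Classical baseline.** A deterministic band-pass segmenter makes the
  whole pipeline testable without trained weights: Gaussian smoothing
  (sigma 4 px) fills the toroid hole, Otsu thresholding with contrast and
  foreground-fraction guards (blank or pure-noise tiles yield nothing)
  extracts foreground, and a distance-transform watershed (peak separation
  8 px) splits touching objects. The score is ring-likeness: the normalized
  contrast between the upper- and lower-quartile intensities inside the
  mask (a toroid contains both a bright annulus and a dark hole) times
  circularity `4*pi*A/P^2`, affinely mapped to `[0.01, 1]`. Its parameters
  are tuned to the synthetic generator's geometry; it is a stand-in for
  testing, not a claim about real-micrograph accuracy.
* **Oracle detector.** Echoes every ground-truth mask fully contained in
  the current window. Because objects no larger than the overlap are always
  fully inside at least one window, the pipeline run with this detector
  must return exactly the ground truth — the plumbing-conservation test.

**Augmentation** (training path): brightness factor uniform in [0.6, 1.8],
contrast uniform in [0.6, 1.8] pivoting on the image mean (the pivot is a
convention choice), spatial scale uniform in [0.5, 1] with zero re-padding
to keep the 512-px frame, independent horizontal/vertical flips at p = 0.5.
Geometric transforms are shared between image and masks; everything is
deterministic per seed.

## Evaluation

A prediction is a true positive iff its IoU with an unmatched ground-truth
object is **strictly greater than 0.5**; matching is greedy in descending
score order, each ground truth consumable once (the standard
order-deterministic discipline; the matching order is otherwise a free
choice). Precision = TP/(TP+FP), recall = TP/n_gt, F1 their harmonic mean
(0 when both are 0; with zero retained predictions precision is reported as
1 with a warning so the curve top is defined).

The precision–recall curve uses **equal-count score bins**: the sorted
scores are split into 100 bins whose counts differ by at most one, each
bin's maximum is a threshold, and metrics are computed over predictions
with score >= threshold (inclusive — this keeps the top bin non-empty; the
alternative exclusive reading is indistinguishable except at ties). Below
100 distinct scores, each distinct score is its own threshold. AP is the
trapezoidal area under the (recall, precision) points after prepending the
(recall 0, precision 1) extrapolation; the curve is *not* extended beyond
the maximum realized recall, and no 11-point or COCO-style interpolation is
applied. The F1-maximizing threshold breaks ties toward the smaller
threshold. A consequence of the binned semantics worth knowing: with `b`
predictions per bin, the lowest threshold excludes `b - 1` predictions, so
a perfect detector's AP is `1 - (b-1)/n` rather than exactly 1; with
per-distinct-score thresholds it is exactly 1.

## Morphometrics

Per bacteriocyte, with hand-measured whole-cell and nuclear areas (um^2)
and the image scale in px/um:

1. cytoplasm area = cell area − nuclear area;
2. density = object count / cytoplasm area (um^-2);
3. object area (um^2) = pixel area / (px per um)^2 — the conversion is
   implemented in the dimensionally correct orientation and the ratio's
   orientation is a config choice at the reader;
4. object "diameter" (um) = sqrt(area / pi) — applied verbatim; note this
   expression is geometrically the **radius** of the equal-area circle, a
   factor-2 naming discrepancy that is preserved deliberately and flagged
   here;
5. occupied fraction = union area of all object masks / cytoplasm area,
   reported both as a fraction and x100 — the union counts multi-way
   overlaps once, so the numerator never exceeds the naive area sum.

Outlier trimming is a **single pass**: z-scores from the sample mean and
n−1 SD of the full input, removing values with |z| > 3 (strict; zero-SD
inputs untouched). Re-running on the kept set may remove more — the
pipeline deliberately runs one pass. Object areas are trimmed within
timepoint; cell-level metrics across all cells.

## Statistics

`compare_groups` routes on Levene's test (classic mean-centered variant):
p >= 0.05 -> one-way ANOVA with Tukey HSD; p < 0.05 -> Kruskal–Wallis with
Dunn's post hoc under Benjamini–Hochberg adjustment. The routing alpha, the
mean-centered Levene variant, and two-sided normal Dunn p-values are
package conventions (reasonable defaults where no single standard exists).
Dunn's test is implemented in-package (rank sums with tie correction) and
cross-checked against an independent rank computation in the tests.
Compact letter displays come from insert-and-absorb over the adjusted
pairwise matrix: groups sharing a letter have adjusted p >= alpha.

`variability_test` compares spread by replacing each value with its
absolute deviation from its group mean, then Kruskal–Wallis + Dunn/BH.
`spearman_trend` is rank correlation against ordered time.
`slope_ci` is OLS with CI = slope ± 1.96 x SE(slope); the multiplier
applies to the **standard error of the slope estimate** — the only reading
of a "±1.96 SD" slope interval that produces a meaningful 95% CI — and r^2
is reported alongside.

Calibration, verified by the acceptance suite: under a seeded complete
null the routed comparison rejects ~5% at alpha = 0.05 (band 3–7% over
1,000 simulations); slope CIs cover a true Gaussian-noise slope ~95%
(93–97% over 1,000 simulations); a 1.5x count step between two cohort
timepoints of 16 cells splits the letter display in >= 95% of 100
replicates.

## Synthetic data

`SceneSpec` defaults define the study conditions: 512-px field, 10 px/um,
60 objects of radius 1.0 ± 0.15 um (floor 0.5 um), annulus thickness half
the radius, zero pairwise overlap, cell ellipse semi-axes 0.46/0.42 of the
side, nucleus 0.13/0.11, background 20, ring intensity 180, Gaussian noise
SD 5 on an 8-bit range. The ~1-um radius at 10 px/um is the scale at which
the detector's smallest 32-px anchor is sensible; 60 objects per 512-px
field matches a densely packed bacteriocyte interior. Ground-truth masks
are **filled disks** — annotators outline whole cells — while the rendering
is an annulus (plus 1-px Gaussian optics blur), so the torus look is a
property of the image only. Placement is seeded rejection sampling inside
the cell ellipse, outside the nucleus, under a pairwise-overlap cap
(closed-form disk intersection); failure after bounded retries raises with
a suggestion to lower density. All randomness flows from a single seed via
`SeedSequence` spawning.

`degrade_truth` produces predictions with known evaluation outcomes (drop
fraction, jitter, clutter disjoint from truth, banded scores), and
`generate_cohort` builds multi-timepoint cohorts with multiplicative count
and radius effects; its fast path skips rendering and lays object masks on
a grid, which is sufficient for morphometric/statistical recovery studies
(counts are Poisson, cell areas get ~8% lognormal variation).

**What the generator does not emulate:** confocal point-spread functions,
depth attenuation, autofluorescence gradients, shot noise statistics,
partially-imaged out-of-plane objects, or annotation disagreement. Passing
tests therefore establish the correctness of the pipeline's geometry,
bookkeeping, evaluation arithmetic, and statistical calibration — not the
accuracy of any detector on real micrographs, which depends on trained
weights outside this package's scope.

## Problem sizes

The test and acceptance workloads use 512–1,024-px scenes with 30–80
objects, 100-replicate power studies, and 1,000-simulation calibration
loops — sizes chosen so the full suite runs comfortably on a single CPU
while keeping binomial uncertainty on the calibrated rates (~0.7% SE at
n = 1,000) well inside the asserted bands.

## Known limitations

* The baseline detector's guards (contrast floor 15, foreground fraction
  cap 0.6) are tuned to the generator's intensity regime; real micrographs
  with bright nuclei or uneven illumination will need the neural adapter.
* Multi-class labels are carried through the data model (mask labels, COCO
  categories) but no multi-channel renderer or multi-class evaluation is
  provided.
* COCO segmentations are polygon lists; masks with interior holes survive
  the result-file round trip (holes stored explicitly) but lose holes when
  forced through COCO's exterior-ring polygon dialect.
* The paper-style equal-count binning makes curve resolution depend on the
  score distribution; with heavy score ties several bins can share one
  threshold.
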