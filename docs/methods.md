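# Methods

## Model and assumptions

The pipeline treats vertebral-body segmentation fusion as a set problem
over binary rasters.  Two candidate sets describe one image: semantic
candidates, obtained by 8-connected component extraction (with hole
filling and a speckle floor) from a per-pixel foreground raster, and
instance candidates, supplied directly as per-object masks with an
optional class tag in {C2, S1, vertebra} and a confidence.  All masks in
one run share the raster dimensions of the input image; nothing is
resampled.  Coordinates are 0-based (row, col) with row increasing
downward, so "down the spine" is increasing row.

The fusion assumes:

* each true vertebral body appears in at least one candidate set as a
  single mask with high boundary fidelity (errors are merges, omissions
  and boundary noise — not gross mislocalisation);
* vertebral bodies in one column have similar areas, which is what
  licenses the area-statistics pickup rule;
* bodies are vertically ordered and non-overlapping, which is what
  licenses top-to-bottom sorting and zip labeling.

## Fusion rules and their parameters

| parameter | default | units | role |
|---|---|---|---|
| `eta` (η) | 0.6 | — | agreement cutoff; strict on both sides (δ > η to union; δ < η with δ_m > η to take over) |
| `lam` (λ) | 2.0 | kept-area σ | half-width of the pickup area window around μ |
| `pickup_dedup_iou` | 0.25 | — | IoU ceiling against kept masks for pickups (and for the union veto) |
| `min_area_px` | 50 | px | speckle floor for semantic component extraction |

η = 0.6 is the recommended working point for the agreement rule; with the
synthetic geometry used here any η in (0.5, 0.75) behaves identically,
because genuine pairs have δ ≈ 0.9+ and two-body blobs δ ≈ 0.48 (see
*Limitations*).  λ = 2 keeps the pickup window wide enough to admit
ordinary inter-vertebral size variation (areas vary by ~±10% in one
column) while rejecting two-body blobs at ~2× the mean area.  The dedup
ceiling 0.25 is deliberately low: distinct vertebrae are disjoint, so any
substantial overlap marks a duplicate, and the same ceiling doubles as the
final separation guarantee.

Design choices where the procedure was genuinely open:

* **One-to-one greedy matching.**  Cross-comparison alone does not define
  an assignment; pairs are matched greedily by descending δ so one
  semantic blob can never union with two instance masks.
* **Union veto.**  A union that would cover another still-unmatched
  candidate by more than η (in the δ_m sense) is refused.  Without this
  guard, a merged two-body blob — whose δ against each constituent is
  ≈ 0.48 — passes the agreement test at low η and re-creates exactly the
  merged-mask failure the fusion exists to repair.  At the default
  η = 0.6 the veto is essentially unreachable, because such pairs already
  fail δ > η.
* **Frozen pickup statistics.**  μ and σ (population form) are computed
  once over the kept areas before the pickup pass; promotions do not
  update them.  Admission therefore does not depend on promotion order,
  which is fixed anyway (closest-to-μ first).
* **Blob disposal.**  A semantic blob implicated in a takeover stays in
  the unused pool and is screened by the pickup rule like any other
  candidate; its doubled area virtually always rejects it.
* **Single-source fallback.**  If one segmenter produced nothing (or no
  rule fired at all), the other side's candidates are kept unfused with a
  warning, rather than failing: a degraded answer beats none for a
  screening tool.  Two empty sources are an error.

## Labeling

The reference body is the highest-confidence instance candidate tagged C2
or S1; if both tags occur (anatomically impossible in one view) the most
confident wins with a warning.  The detection is localised among the fused
masks by maximum IoU with a 0.5 floor.  Labels zip along the sorted
column through the canonical vocabulary C2…C7, T1…T12, L1…L5, S1; the
vocabulary is capped at both ends (C1 is never emitted, nothing below S1)
and surplus masks are left unlabeled, as are masks above C2 / below S1.
Without a reference the whole spine is returned unlabeled — an explicit
"don't know", not an error.

A single unrecovered mid-column body shifts every label beyond it by one.
This failure mode is inherent to counting-based identification and is
asserted in the test suite so regressions surface.

## Evaluation

Per-class Dice is computed on the label-matched mask pair (0 when a
ground-truth class has no prediction); overall Dice is the unweighted
mean over ground-truth classes.  Panoptic quality uses label-equality
matching with an IoU threshold strictly above 0.5 (which makes matches
unique); PQ, SQ and RQ are reported per class and pooled, at 0.7 and 0.8
by default.  Predictions for classes absent from the ground truth count
as false positives unless `ignore_unannotated` is set — both behaviours
exist because partially annotated datasets make the strict reading
unfairly pessimistic.

## Synthetic fixtures

The generator emulates what the rules actually consume: a column of 5–9
convex quadrilateral bodies (8 landmarks each: corners plus edge
midpoints) along a smooth sinusoidal curve in a 512×256 raster, ~6 px
inter-body gaps, per-body size wobble of ±8%, a cone-shaped C2 or
triangular S1 at the reference end.  The semantic corruption bridges each
gap independently with probability `p_merge` and flips boundary-band
pixels; the instance corruption drops each body independently with
probability `p_drop` — doubled at the column ends, mirroring how object
detectors miss partially visible bodies — and tags the surviving
reference with confidence drawn from U[0.7, 1.0].  All randomness flows
from explicit integer seeds; semantic and instance corruptions use
decorrelated streams of one seed.

What the fixtures do *not* model: radiographic intensity and texture,
projective distortion, pathology-specific shape change, inter-reader
annotation variability, and gross segmenter hallucinations.  Passing
tests demonstrate the correctness and robustness of the fusion logic
under its stated assumptions — not clinical performance.

## Numerical conventions

* All set operations are exact pixel counts (bounding-box accelerated);
  a pixel belongs to a polygon when the polygon covers its integer
  (row, col) center, boundary included.  An axis-aligned rectangle with
  corners at rows 10–40, cols 10–30 fills exactly 31×21 pixels.
* Connectivity is 8-connected everywhere.
* Sorting ties (equal centroid row) break by centroid column, then by
  larger area; all rule orderings are total, so results are independent
  of input order.
* SQ is defined as 0 when there are no true positives; an evaluation
  with no TP, FP or FN anywhere is an error.
* Landmark polygons are taken in stored order; a flag re-orders points by
  angle about the centroid for datasets with unknown corner conventions.

## Problem sizes

The default verification suites use 200 corrupted spines (~1,450
vertebrae) for recovery and separation properties, 100 clean spines for
the fixed-point property, 500 random mask pairs for brute-force oracle
equivalence, 1,000 random match sets for the PQ identity, and 1,000
corruption seeds for calibration.  The full test suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

* **Low-η sensitivity under heavy merging.**  The agreement and takeover
  rules partition pairs by δ relative to η.  A blob of two similar-sized
  merged bodies has δ ≈ v/(2v + bridge) ∈ (0.4, 0.5) against each
  constituent: for η above that band the takeover rule separates it, but
  for η below (e.g. 0.3) the pair *passes* the agreement test and the
  union re-merges the bodies; when only one constituent exists in the
  instance set, no veto can detect this.  On the standard corruption
  suite (merge and drop probability 0.2), recovery at η = 0.3 is
  measurably lower (~8 pp) than at η ∈ {0.5, 0.7}.  Threshold choices
  below 0.5 are therefore not recommended when merging is frequent.
* Reference bodies are smaller than regular bodies (cone/triangle), so
  when the instance segmenter drops the reference, the area-window pickup
  usually cannot recover it from the semantic side and the spine stays
  unlabeled — consistent with treating the reference detection as a hard
  prerequisite of identification.
* Exactly two input segmenters; the rules do not generalise as written to
  three or more candidate sets.
* Counting-based labeling cannot recover from a truly missing mid-column
  body (label shift), and never emits C1 or sacral bodies below S1.
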