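"""Evaluation of labeled vertebral-body predictions.

Two complementary views of quality:

* **Per-class Dice** — mask overlap per anatomical label, the standard
  segmentation score ``2|A∩B| / (|A|+|B|)``.
* **Panoptic Quality (PQ)** — joint segmentation + identification score::

      PQ = Σ_{(p,g) ∈ TP} IoU(p,g) / (|TP| + ½|FP| + ½|FN|)
         = SQ × RQ,   SQ = mean TP IoU,   RQ = |TP| / (|TP| + ½|FP| + ½|FN|)

  where a prediction and a ground-truth vertebra form a true positive only
  when they carry the *same anatomical label* and overlap above the IoU
  threshold.  A one-off label shift therefore scores zero — identification
  errors are treated as part of segmentation quality, which is the point
  of reporting PQ alongside Dice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .geometry import InstanceMask, intersection_area, iou

logger = logging.getLogger("spinefuse")

LabeledMasks = list[tuple[str, InstanceMask]]


class EvaluationError(ValueError):
    """Evaluation on incompatible or empty inputs."""


def dice(a: InstanceMask, b: InstanceMask) -> float:
    """Dice coefficient ``2|A∩B| / (|A|+|B|)`` of two masks."""
    return 2.0 * intersection_area(a, b) / (a.area + b.area)


@dataclass
class MatchSet:
    """TP/FP/FN bookkeeping at one IoU threshold.

    Every TP pair satisfies ``label(pred) == label(gt)`` and
    ``IoU > iou_threshold``; with a threshold above 0.5 and unique labels
    per spine the matching is unambiguous.
    """

    tp: list[tuple[InstanceMask, InstanceMask, float]] = field(default_factory=list)
    fp: list[tuple[str, InstanceMask]] = field(default_factory=list)
    fn: list[tuple[str, InstanceMask]] = field(default_factory=list)
    iou_threshold: float = 0.5

    def __add__(self, other: "MatchSet") -> "MatchSet":
        if self.iou_threshold != other.iou_threshold:
            raise EvaluationError("cannot pool MatchSets at different thresholds")
        return MatchSet(
            tp=self.tp + other.tp, fp=self.fp + other.fp,
            fn=self.fn + other.fn, iou_threshold=self.iou_threshold,
        )


@dataclass
class EvalReport:
    """Per-class and pooled scores at one matching threshold."""

    iou_threshold: float
    dice_per_class: dict[str, float]
    dice_overall: float
    pq_per_class: dict[str, float]
    sq_per_class: dict[str, float]
    rq_per_class: dict[str, float]
    pq: float
    sq: float
    rq: float
    matches: MatchSet | None = None

    def as_dict(self) -> dict:
        return {
            "iou_threshold": self.iou_threshold,
            "dice_per_class": self.dice_per_class,
            "dice_overall": self.dice_overall,
            "pq_per_class": self.pq_per_class,
            "sq_per_class": self.sq_per_class,
            "rq_per_class": self.rq_per_class,
            "pq": self.pq,
            "sq": self.sq,
            "rq": self.rq,
        }


def count_recovered(
    gt_masks: list[InstanceMask],
    candidates: list[InstanceMask],
    iou_threshold: float = 0.5,
) -> int:
    """Number of ground-truth masks represented among *candidates*.

    Greedy one-to-one geometric matching (labels ignored) in descending
    IoU; a ground-truth mask counts as recovered when its match reaches
    ``iou_threshold``.  This is the recall-style score used to compare a
    fused result against each corrupted source.
    """
    pairs = []
    for i, g in enumerate(gt_masks):
        for j, c in enumerate(candidates):
            v = iou(g, c)
            if v >= iou_threshold:
                pairs.append((v, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g: set[int] = set()
    used_c: set[int] = set()
    n = 0
    for _, i, j in pairs:
        if i in used_g or j in used_c:
            continue
        used_g.add(i)
        used_c.add(j)
        n += 1
    return n


def match_instances(
    preds: LabeledMasks,
    gts: LabeledMasks,
    iou_threshold: float,
    ignore_unannotated: bool = False,
) -> MatchSet:
    """Match predictions to ground truth by label identity and IoU.

    A pair matches iff the anatomical labels are equal and IoU exceeds
    ``iou_threshold`` (which must exceed 0.5 so matches are unique).
    Unmatched predictions count as false positives — unless
    ``ignore_unannotated`` drops predictions whose label has no ground
    truth at all, for datasets with known-incomplete annotation.
    Unmatched ground-truth vertebrae count as false negatives.
    """
    if not iou_threshold > 0.5:
        raise EvaluationError(
            f"iou_threshold must exceed 0.5 for unique matching, got {iou_threshold}"
        )
    gt_by_label = {lab: m for lab, m in gts}
    if len(gt_by_label) != len(gts):
        raise EvaluationError("duplicate labels in ground truth")
    pred_by_label = {lab: m for lab, m in preds}
    if len(pred_by_label) != len(preds):
        raise EvaluationError("duplicate labels in prediction")

    ms = MatchSet(iou_threshold=iou_threshold)
    matched_gt: set[str] = set()
    for lab, pm in preds:
        gm = gt_by_label.get(lab)
        if gm is not None:
            ov = iou(pm, gm)
            if ov > iou_threshold:
                ms.tp.append((pm, gm, ov))
                matched_gt.add(lab)
                continue
        if gm is None and ignore_unannotated:
            continue
        ms.fp.append((lab, pm))
    for lab, gm in gts:
        if lab not in matched_gt:
            ms.fn.append((lab, gm))
    return ms


def panoptic_quality(match: MatchSet) -> tuple[float, float, float]:
    """Compute ``(PQ, SQ, RQ)`` from a match set.

    SQ is defined as 0 when there is no true positive.  An entirely empty
    match set (no TP, FP or FN) is an error — there was nothing to
    evaluate.
    """
    n_tp, n_fp, n_fn = len(match.tp), len(match.fp), len(match.fn)
    if n_tp + n_fp + n_fn == 0:
        raise EvaluationError("empty match set: nothing to evaluate")
    denom = n_tp + 0.5 * n_fp + 0.5 * n_fn
    iou_sum = sum(v for _, _, v in match.tp)
    pq = iou_sum / denom
    sq = iou_sum / n_tp if n_tp else 0.0
    rq = n_tp / denom
    return pq, sq, rq


def evaluate(
    preds: LabeledMasks,
    gts: LabeledMasks,
    thresholds: list[float] = (0.7, 0.8),
    ignore_unannotated: bool = False,
) -> dict[float, EvalReport]:
    """Score a labeled prediction against labeled ground truth.

    Per-class Dice is computed on the label-matched mask pair (0 when a
    ground-truth class has no prediction); overall Dice is the unweighted
    mean over classes present in the ground truth.  PQ/SQ/RQ are reported
    per class and pooled over all classes, at each matching threshold.
    """
    if not gts:
        raise EvaluationError("ground truth is empty")
    shapes = {m.shape for _, m in list(preds) + list(gts)}
    if len(shapes) > 1:
        raise EvaluationError(f"prediction/ground-truth resolutions differ: {shapes}")

    pred_by_label = {lab: m for lab, m in preds}
    dice_per_class: dict[str, float] = {}
    for lab, gm in gts:
        pm = pred_by_label.get(lab)
        dice_per_class[lab] = dice(pm, gm) if pm is not None else 0.0
    dice_overall = sum(dice_per_class.values()) / len(dice_per_class)

    reports: dict[float, EvalReport] = {}
    for thr in thresholds:
        pooled = match_instances(preds, gts, thr, ignore_unannotated)
        pq, sq, rq = panoptic_quality(pooled)
        classes = sorted({lab for lab, _ in gts} | {lab for lab, _ in pooled.fp})
        pq_c: dict[str, float] = {}
        sq_c: dict[str, float] = {}
        rq_c: dict[str, float] = {}
        for lab in classes:
            sub_pred = [(l, m) for l, m in preds if l == lab]
            sub_gt = [(l, m) for l, m in gts if l == lab]
            sub = match_instances(sub_pred, sub_gt, thr, ignore_unannotated)
            if len(sub.tp) + len(sub.fp) + len(sub.fn) == 0:
                continue
            pq_c[lab], sq_c[lab], rq_c[lab] = panoptic_quality(sub)
        reports[thr] = EvalReport(
            iou_threshold=thr,
            dice_per_class=dice_per_class,
            dice_overall=dice_overall,
            pq_per_class=pq_c, sq_per_class=sq_c, rq_per_class=rq_c,
            pq=pq, sq=sq, rq=rq,
            matches=pooled,
        )
    return reports
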