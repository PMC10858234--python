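"""Anatomical labeling of fused vertebral-body masks.

Individual vertebral bodies look too similar to name in isolation, but two
are visually distinctive: C2 (the axis; cone-shaped, topmost body visible
on a cervical view) and S1 (first sacral; triangular, bottom-most body on
a lumbar view).  The instance segmenter is assumed to tag these reference
bodies.  Labeling then exploits the fixed anatomical order of the spine:
anchor on the reference and "zip" along the sorted column — down from C2
through C3..C7 into the thoracic names, or up from S1 through L5..L1 into
T12, T11, and so on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ensemble import EnsembleConfig, EnsembleResult, run_ensemble
from .geometry import InstanceMask, iou

logger = logging.getLogger("spinefuse")

#: Full top-to-bottom anatomical vocabulary covered by lateral views.
#: C1 is never emitted (not reliably visible), and nothing below S1.
CANONICAL_ORDER: tuple[str, ...] = (
    "C2", "C3", "C4", "C5", "C6", "C7",
    "T1", "T2", "T3", "T4", "T5", "T6",
    "T7", "T8", "T9", "T10", "T11", "T12",
    "L1", "L2", "L3", "L4", "L5",
    "S1",
)


class ReferenceNotFound(RuntimeError):
    """A tagged reference vertebra could not be localised among the fused masks."""


@dataclass
class LabeledSpine:
    """Fused masks with anatomical names.

    ``vertebrae`` is ordered top-to-bottom; labels are unique and follow
    :data:`CANONICAL_ORDER`.  Masks beyond the reference in the
    non-labeling direction (above C2 / below S1) are never guessed and sit
    in ``unlabeled``; when no reference was detected all masks do and
    ``reference`` is ``"none"``.
    """

    vertebrae: list[tuple[InstanceMask, str]]
    reference: str = "none"            # C2 | S1 | none
    direction: str = "none"            # zip_down | zip_up | none
    unlabeled: list[InstanceMask] = field(default_factory=list)
    ensemble: EnsembleResult | None = None

    @property
    def labels(self) -> list[str]:
        return [lab for _, lab in self.vertebrae]


def find_reference(
    instance_masks: list[InstanceMask],
) -> tuple[str, InstanceMask | None]:
    """Pick the reference vertebra from tagged instance candidates.

    Returns the highest-confidence mask tagged C2 or S1 (untagged runs
    return ``("none", None)`` — a valid outcome, the spine simply stays
    unlabeled).  If both reference classes appear, the single most
    confident detection wins and a warning is logged; cervical and lumbar
    views never legitimately contain both.
    """
    refs = [m for m in instance_masks if m.class_tag in ("C2", "S1")]
    if not refs:
        return "none", None
    classes = {m.class_tag for m in refs}
    best = max(refs, key=lambda m: (m.confidence or 0.0))
    if len(classes) > 1:
        logger.warning(
            "both C2 and S1 tags present; keeping the most confident (%s, "
            "confidence %.2f)", best.class_tag, best.confidence or 0.0,
        )
    return best.class_tag, best


def assign_labels(
    sorted_masks: list[InstanceMask],
    ref_class: str,
    ref_mask: InstanceMask | None,
    ensemble: EnsembleResult | None = None,
) -> LabeledSpine:
    """Zip anatomical names along a top-to-bottom sorted mask column.

    The reference detection is first localised among ``sorted_masks`` by
    maximum IoU (must exceed 0.5, else :class:`ReferenceNotFound`).  With
    C2 as anchor, names run down the canonical order; with S1, up.  The
    label vocabulary is capped at C2..S1 — surplus masks beyond it are
    left unlabeled with a warning.
    """
    if ref_class == "none" or ref_mask is None:
        return LabeledSpine(
            vertebrae=[], reference="none", direction="none",
            unlabeled=list(sorted_masks), ensemble=ensemble,
        )
    if ref_class not in ("C2", "S1"):
        raise ValueError(f"reference class must be C2, S1 or none, got {ref_class!r}")
    if not sorted_masks:
        raise ReferenceNotFound("no fused masks to label")

    ious = [iou(ref_mask, m) for m in sorted_masks]
    idx = int(np.argmax(ious))
    if ious[idx] <= 0.5:
        raise ReferenceNotFound(
            f"reference {ref_class} matches no fused mask at IoU > 0.5 "
            f"(best {ious[idx]:.3f})"
        )

    vertebrae: list[tuple[InstanceMask, str]] = []
    unlabeled: list[InstanceMask] = []
    if ref_class == "C2":
        direction = "zip_down"
        unlabeled.extend(sorted_masks[:idx])
        names = CANONICAL_ORDER  # starts at C2
        below = sorted_masks[idx:]
        for k, m in enumerate(below):
            if k < len(names):
                vertebrae.append((m, names[k]))
            else:
                unlabeled.append(m)
        if len(below) > len(names):
            logger.warning(
                "%d masks below C2 exceed the label vocabulary; %d left "
                "unlabeled", len(below), len(below) - len(names),
            )
    else:  # S1: zip upward
        direction = "zip_up"
        unlabeled.extend(sorted_masks[idx + 1:])
        names = CANONICAL_ORDER[::-1]  # starts at S1
        above = sorted_masks[idx::-1]  # reference upward
        labeled_up: list[tuple[InstanceMask, str]] = []
        for k, m in enumerate(above):
            if k < len(names):
                labeled_up.append((m, names[k]))
            else:
                unlabeled.append(m)
        if len(above) > len(names):
            logger.warning(
                "%d masks above S1 exceed the label vocabulary; %d left "
                "unlabeled", len(above), len(above) - len(names),
            )
        vertebrae = labeled_up[::-1]  # restore top-to-bottom order

    return LabeledSpine(
        vertebrae=vertebrae, reference=ref_class, direction=direction,
        unlabeled=unlabeled, ensemble=ensemble,
    )


def label_pipeline(
    semantic_raster: np.ndarray,
    instance_masks: list[InstanceMask],
    cfg: EnsembleConfig | None = None,
) -> LabeledSpine:
    """Fuse the two segmentations, then label anatomically.

    Runs :func:`~spinefuse.ensemble.run_ensemble`, locates the reference
    among the raw instance detections, and zips labels along the fused,
    sorted column.  Provenance and warnings carry through; a missing
    reference yields an unlabeled spine rather than an error.
    """
    result = run_ensemble(semantic_raster, instance_masks, cfg)
    ref_class, ref_mask = find_reference(instance_masks)
    return assign_labels(result.kept, ref_class, ref_mask, ensemble=result)
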