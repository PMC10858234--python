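"""Rule-based fusion of semantic and instance vertebral-body candidates.

A per-pixel (semantic) segmenter reliably finds every vertebral body but
merges closely spaced neighbours into one blob; a per-object (instance)
segmenter keeps vertebrae separated but misses partially visible ones.
The fusion runs three rules over the two candidate sets and keeps one
separated mask per vertebra:

A. *Agreement* — cross-compare all (semantic, instance) pairs; pairs whose
   agreement δ = area(∩)/max(areas) exceeds the threshold η are unioned
   and kept.
C. *Takeover* — a remaining instance mask covered almost entirely by some
   remaining semantic mask (δ_m = area(∩)/area(instance) > η) while the
   agreement is low (δ < η) marks a merged semantic blob; the instance
   mask is taken directly.
P. *Pickup* — remaining candidates whose area lies within λ·σ of the mean
   kept-mask area are promoted, recovering vertebrae one source missed.

The kept masks are finally sorted top-to-bottom for anatomical labeling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    InstanceMask,
    agreement,
    extract_instances,
    instance_overlap_fraction,
    iou,
    union,
)

logger = logging.getLogger("spinefuse")


class EnsembleFailure(RuntimeError):
    """The fusion could not produce any kept mask."""


@dataclass(frozen=True)
class EnsembleConfig:
    """Tunable thresholds of the fusion rules.

    eta
        Agreement cutoff η for rules A and C, strict on both sides
        (δ > η to union, δ < η with δ_m > η to take over).  0.6 is the
        recommended working point; results are stable over a wide band.
    lam
        Pickup window half-width λ in units of the kept-area standard
        deviation.
    pickup_dedup_iou
        A candidate is only picked up (and a union only formed) when it
        does not duplicate / swallow an already-separated mask; this is
        the IoU ceiling used for that screen.
    min_area_px
        Speckle floor for semantic component extraction, in pixels at the
        working resolution.
    """

    eta: float = 0.6
    lam: float = 2.0
    pickup_dedup_iou: float = 0.25
    min_area_px: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.eta < 1.0:
            raise ValueError(f"eta must lie in (0, 1), got {self.eta}")
        if self.lam <= 0:
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not 0.0 <= self.pickup_dedup_iou <= 1.0:
            raise ValueError("pickup_dedup_iou must lie in [0, 1]")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be non-negative")


@dataclass
class EnsembleResult:
    """Fusion output: ordered kept masks plus bookkeeping.

    ``kept`` is sorted top-to-bottom; every member's provenance records the
    rule that produced it.  ``mu_area``/``sigma_area`` are the kept-area
    statistics the pickup rule screened against (population σ, frozen
    before the pickup pass).
    """

    kept: list[InstanceMask]
    unused: list[InstanceMask]
    counts: dict[str, int] = field(default_factory=dict)
    mu_area: float = 0.0
    sigma_area: float = 0.0


# -- rule A: agreement unions ----------------------------------------------


def select_agreement_pairs(
    semantic: list[InstanceMask],
    instance: list[InstanceMask],
    cfg: EnsembleConfig,
) -> tuple[list[InstanceMask], list[InstanceMask], list[InstanceMask]]:
    """Union cross-matched candidate pairs that agree (δ > η).

    Matching is one-to-one and greedy in descending δ, so one semantic
    blob can never union with two instance masks.  A union is additionally
    vetoed when it would cover another still-unmatched candidate by more
    than η in the δ_m sense: such a union would swallow a separable
    vertebra, re-creating the merged-blob failure the fusion exists to
    undo.  Returns ``(kept_unions, semantic_rest, instance_rest)``.
    """
    pairs: list[tuple[float, int, int]] = []
    for i, s in enumerate(semantic):
        for j, m in enumerate(instance):
            d = agreement(s, m)
            if d > cfg.eta:
                pairs.append((d, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    kept: list[InstanceMask] = []
    sem_used = [False] * len(semantic)
    inst_used = [False] * len(instance)
    for d, i, j in pairs:
        if sem_used[i] or inst_used[j]:
            continue
        u = union(semantic[i], instance[j])
        swallowed = None
        for k, m in enumerate(instance):
            if k != j and not inst_used[k] and instance_overlap_fraction(u, m) > cfg.eta:
                swallowed = ("instance", k)
                break
        if swallowed is None:
            for k, s in enumerate(semantic):
                if k != i and not sem_used[k] and instance_overlap_fraction(u, s) > cfg.eta:
                    swallowed = ("semantic", k)
                    break
        if swallowed is not None:
            logger.debug(
                "agreement union (sem %d, inst %d, delta=%.3f) vetoed: would "
                "cover unmatched %s candidate %d", i, j, d, *swallowed
            )
            continue
        sem_used[i] = True
        inst_used[j] = True
        kept.append(u)
        logger.debug("agreement union: sem %d + inst %d (delta=%.3f)", i, j, d)

    sem_rest = [s for s, used in zip(semantic, sem_used) if not used]
    inst_rest = [m for m, used in zip(instance, inst_used) if not used]
    return kept, sem_rest, inst_rest


# -- rule C: instance takeover on merged blobs ------------------------------


def separate_overlapping(
    semantic_rest: list[InstanceMask],
    instance_rest: list[InstanceMask],
    cfg: EnsembleConfig,
) -> tuple[list[InstanceMask], list[InstanceMask], list[InstanceMask]]:
    """Take instance masks that sit inside a merged semantic blob.

    An instance mask is kept (provenance ``instance_takeover``) when some
    remaining semantic mask covers it well (δ_m > η) yet agrees poorly
    (δ < η) — the signature of a blob spanning several vertebrae.  The
    implicated semantic blob stays in the rest list; the pickup rule's
    area screen disposes of it later.
    """
    kept: list[InstanceMask] = []
    inst_left: list[InstanceMask] = []
    for m in instance_rest:
        taken = False
        for s in semantic_rest:
            if (
                agreement(s, m) < cfg.eta
                and instance_overlap_fraction(s, m) > cfg.eta
            ):
                taken = True
                break
        if taken:
            kept.append(m.with_provenance("instance_takeover"))
            logger.debug("instance takeover: mask at %s", m.centroid)
        else:
            inst_left.append(m)
    return kept, list(semantic_rest), inst_left


# -- rule P: pickup of missed vertebrae -------------------------------------


def pickup_missed(
    kept: list[InstanceMask],
    unused: list[InstanceMask],
    cfg: EnsembleConfig,
) -> tuple[list[InstanceMask], list[InstanceMask], float, float]:
    """Promote unused candidates whose area matches the kept population.

    The mean μ and population standard deviation σ of the kept-mask areas
    are computed once; an unused mask is promoted iff |area − μ| ≤ λ·σ and
    it does not duplicate an already-kept mask (IoU ≤ ``pickup_dedup_iou``
    against every kept mask, promotions included).  Candidates are
    processed closest-to-μ first; the statistics are not recomputed during
    the pass, so admission does not depend on promotion order.

    Returns ``(kept_out, still_unused, mu, sigma)``.
    """
    if not kept:
        raise EnsembleFailure("pickup requires at least one kept mask")
    areas = np.array([m.area for m in kept], dtype=float)
    mu = float(areas.mean())
    sigma = float(areas.std())  # population sigma, frozen for the pass

    order = sorted(
        range(len(unused)),
        key=lambda i: (abs(unused[i].area - mu), unused[i].centroid),
    )
    kept_out = list(kept)
    promoted = [False] * len(unused)
    for i in order:
        cand = unused[i]
        if abs(cand.area - mu) > cfg.lam * sigma:
            continue
        if any(iou(cand, k) > cfg.pickup_dedup_iou for k in kept_out):
            logger.debug("pickup rejected (duplicate): mask at %s", cand.centroid)
            continue
        kept_out.append(cand.with_provenance("pickup"))
        promoted[i] = True
        logger.debug(
            "pickup: mask area %d within mu=%.1f +/- %.1f", cand.area, mu,
            cfg.lam * sigma,
        )
    still_unused = [u for u, p in zip(unused, promoted) if not p]
    return kept_out, still_unused, mu, sigma


# -- final ordering ---------------------------------------------------------


def sort_masks(kept: list[InstanceMask]) -> list[InstanceMask]:
    """Sort masks top-to-bottom (centroid row, then column, then −area)."""
    return sorted(kept, key=lambda m: (m.centroid[0], m.centroid[1], -m.area))


# -- full procedure ---------------------------------------------------------


def run_ensemble(
    semantic_raster: np.ndarray,
    instance_masks: list[InstanceMask],
    cfg: EnsembleConfig | None = None,
) -> EnsembleResult:
    """Run the full fusion: extract, agree, take over, pick up, sort.

    Degenerate inputs degrade gracefully: when one segmenter produced
    nothing, all candidates from the other are kept (provenance
    ``pickup``) with a warning; only two empty sources are an error.
    """
    cfg = cfg or EnsembleConfig()
    semantic = extract_instances(semantic_raster, cfg.min_area_px)
    instance = list(instance_masks)

    if not semantic and not instance:
        raise EnsembleFailure("no candidate masks from either segmenter")

    if not semantic or not instance:
        side = "semantic" if semantic else "instance"
        logger.warning(
            "single-source fallback: only the %s segmenter produced "
            "candidates; keeping all of them unfused", side
        )
        kept = [m.with_provenance("pickup") for m in (semantic or instance)]
        areas = np.array([m.area for m in kept], dtype=float)
        return EnsembleResult(
            kept=sort_masks(kept),
            unused=[],
            counts={"agreement_union": 0, "instance_takeover": 0,
                    "pickup": len(kept)},
            mu_area=float(areas.mean()),
            sigma_area=float(areas.std()),
        )

    kept_a, sem_rest, inst_rest = select_agreement_pairs(semantic, instance, cfg)
    kept_c, sem_rest, inst_rest = separate_overlapping(sem_rest, inst_rest, cfg)
    kept = kept_a + kept_c

    if not kept:
        # Both sources produced candidates but no rule fired (e.g. the two
        # segmentations are disjoint).  Anchor statistics are undefined, so
        # fall back to the more complete source rather than failing.
        logger.warning(
            "no agreement or takeover fired; falling back to semantic "
            "candidates"
        )
        kept = [m.with_provenance("pickup") for m in semantic]
        areas = np.array([m.area for m in kept], dtype=float)
        return EnsembleResult(
            kept=sort_masks(kept),
            unused=list(instance),
            counts={"agreement_union": 0, "instance_takeover": 0,
                    "pickup": len(kept)},
            mu_area=float(areas.mean()),
            sigma_area=float(areas.std()),
        )

    unused = sort_masks(sem_rest + inst_rest)
    kept, unused, mu, sigma = pickup_missed(kept, unused, cfg)
    kept = sort_masks(kept)

    counts = {"agreement_union": 0, "instance_takeover": 0, "pickup": 0}
    for m in kept:
        counts[m.provenance] += 1
    logger.info(
        "ensemble kept %d masks (%d unions, %d takeovers, %d pickups), "
        "%d unused", len(kept), counts["agreement_union"],
        counts["instance_takeover"], counts["pickup"], len(unused),
    )
    return EnsembleResult(kept=kept, unused=unused, counts=counts,
                          mu_area=mu, sigma_area=sigma)
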