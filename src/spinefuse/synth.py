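"""Synthetic spine fixtures: ground truth plus corrupted segmentations.

Real lateral spinal X-rays and trained segmentation networks are not
needed to exercise the fusion rules — the rules only see areas, overlaps
and vertical order.  This module generates:

* a **ground-truth column** of 5-9 convex quadrilateral vertebral bodies
  stacked along a smooth curve, each outlined by 8 landmarks (corners plus
  edge midpoints) and labeled anatomically; the reference body has its
  distinctive shape (cone-like C2 at the top of cervical columns,
  triangular S1 at the bottom of lumbar ones);
* a **semantic corruption** emulating a per-pixel segmenter: the union of
  all bodies, with each inter-vertebral gap independently bridged with
  probability ``p_merge`` (merged neighbours become one blob) and boundary
  noise applied;
* an **instance corruption** emulating a per-object segmenter: each body
  independently dropped with probability ``p_drop`` — doubled for the
  partially visible topmost/bottommost bodies, which is what object
  detectors actually miss — with boundary noise on the survivors and a
  class tag plus confidence on the reference.

All randomness flows from explicit integer seeds; the same spec always
yields bit-identical rasters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .fileio import (
    GroundTruthAnnotation,
    save_annotation,
    save_instance_set,
    write_mask_png,
)
from .geometry import EIGHT_CONN, InstanceMask, polygon_to_raster
from .identify import CANONICAL_ORDER

logger = logging.getLogger("spinefuse")

_TOP_MARGIN = 30  # px kept clear above/below the column
_BASE_WIDTH_FRAC = 0.34  # mean body width as a fraction of image width
_CONE_TOP_FRAC = 0.45  # C2: top edge width fraction (cone shape)
_TRI_BOTTOM_FRAC = 0.18  # S1: bottom edge width fraction (triangular)
_JITTER_FLIP_P = 0.35  # boundary-band pixel flip probability


@dataclass(frozen=True)
class SpineSpec:
    """Geometry of one synthetic spine."""

    region: str = "cervical"  # cervical | lumbar
    n_vertebrae: int = 7
    image_size: tuple[int, int] = (512, 256)
    curve_amplitude: float = 18.0
    gap_px: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region not in ("cervical", "lumbar"):
            raise ValueError(f"region must be cervical or lumbar, got {self.region!r}")
        if not 5 <= self.n_vertebrae <= 9:
            raise ValueError("n_vertebrae must lie in 5..9")
        if self.gap_px < 0:
            raise ValueError("gap_px must be non-negative")

    @property
    def labels(self) -> list[str]:
        """Top-to-bottom anatomical labels for this spec."""
        if self.region == "cervical":
            return list(CANONICAL_ORDER[: self.n_vertebrae])
        return list(CANONICAL_ORDER[-self.n_vertebrae:])


@dataclass(frozen=True)
class CorruptionSpec:
    """Failure-mode parameters for the two corrupted segmentations."""

    p_merge: float = 0.2
    p_drop: float = 0.2
    boundary_jitter_px: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_merge <= 1.0 or not 0.0 <= self.p_drop <= 1.0:
            raise ValueError("corruption probabilities must lie in [0, 1]")
        if self.boundary_jitter_px < 0:
            raise ValueError("boundary_jitter_px must be non-negative")


# -- ground truth -----------------------------------------------------------


def _vertebra_polygon(
    rt: float, rb: float, col_center: float, width: float,
    top_frac: float, bottom_frac: float,
) -> np.ndarray:
    """8-landmark trapezoid: corners plus edge midpoints, clockwise from
    the top-left corner."""
    tl = (rt, col_center - width * top_frac / 2)
    tr = (rt, col_center + width * top_frac / 2)
    br = (rb, col_center + width * bottom_frac / 2)
    bl = (rb, col_center - width * bottom_frac / 2)
    tm = (rt, col_center)
    rm = ((rt + rb) / 2, (tr[1] + br[1]) / 2)
    bm = (rb, col_center)
    lm = ((rt + rb) / 2, (tl[1] + bl[1]) / 2)
    return np.array([tl, tm, tr, rm, br, bm, bl, lm], dtype=float)


def generate_spine(
    spec: SpineSpec,
) -> tuple[GroundTruthAnnotation, list[InstanceMask]]:
    """Generate one labeled ground-truth column.

    Returns the 8-landmark annotation and the per-vertebra masks
    (top-to-bottom, pairwise disjoint).  Deterministic under the spec's
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    n = spec.n_vertebrae
    slot = (H - 2 * _TOP_MARGIN - (n - 1) * spec.gap_px) / n
    if slot < 12:
        raise ValueError(
            f"image height {H} cannot hold {n} vertebrae at gap {spec.gap_px}"
        )
    labels = spec.labels
    vertebrae: list[tuple[str, np.ndarray]] = []
    masks: list[InstanceMask] = []
    for i in range(n):
        t = i / max(n - 1, 1)
        rt = _TOP_MARGIN + i * (slot + spec.gap_px)
        height = slot * (1.0 - rng.uniform(0.0, 0.08))
        rb = rt + height
        col_center = (
            W / 2
            + spec.curve_amplitude * np.sin(np.pi * (t - 0.5))
            + rng.uniform(-2.0, 2.0)
        )
        width = _BASE_WIDTH_FRAC * W * (1.0 + rng.uniform(-0.08, 0.08))
        top_frac = rng.uniform(0.88, 1.0)
        bottom_frac = rng.uniform(0.88, 1.0)
        if spec.region == "cervical" and i == 0:
            top_frac = _CONE_TOP_FRAC  # C2 cone
        if spec.region == "lumbar" and i == n - 1:
            bottom_frac = _TRI_BOTTOM_FRAC  # S1 triangle
        poly = _vertebra_polygon(rt, rb, col_center, width, top_frac, bottom_frac)
        vertebrae.append((labels[i], poly))
        masks.append(
            InstanceMask(polygon_to_raster(poly, (H, W)), source="ground_truth")
        )
    occupancy = np.zeros((H, W), dtype=np.int32)
    for m in masks:
        occupancy += m.pixels
    if occupancy.max() > 1:
        raise ValueError("generated vertebrae overlap; reduce size or count")
    ann = GroundTruthAnnotation(
        vertebrae=vertebrae, image_size=(H, W),
        source_id=f"synthetic/{spec.region}/seed{spec.seed}",
    )
    return ann, masks


# -- corruptions ------------------------------------------------------------


def _crop_slices(raster: np.ndarray, pad: int) -> tuple[slice, slice]:
    rows = np.flatnonzero(raster.any(axis=1))
    cols = np.flatnonzero(raster.any(axis=0))
    H, W = raster.shape
    return (
        slice(max(rows[0] - pad, 0), min(rows[-1] + pad + 1, H)),
        slice(max(cols[0] - pad, 0), min(cols[-1] + pad + 1, W)),
    )


def _jitter_raster(
    raster: np.ndarray, rng: np.random.Generator, jitter_px: float
) -> np.ndarray:
    """Flip pixels within ±jitter of the boundary (boundary noise).

    The random field is drawn over the full raster so the draw sequence
    does not depend on mask extents.
    """
    if jitter_px <= 0:
        return raster
    field = rng.random(raster.shape) < _JITTER_FLIP_P
    r = int(round(jitter_px))
    ball = np.ones((2 * r + 1, 2 * r + 1), dtype=bool)
    sl = _crop_slices(raster, r + 1)
    crop = raster[sl]
    band = ndimage.binary_dilation(crop, ball) ^ ndimage.binary_erosion(crop, ball)
    out = raster.copy()
    out[sl] = crop ^ (band & field[sl])
    return out


def _largest_component(raster: np.ndarray) -> np.ndarray:
    sl = _crop_slices(raster, 1)
    labels, n = ndimage.label(raster[sl], structure=EIGHT_CONN)
    if n <= 1:
        return raster
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    out = np.zeros_like(raster)
    out[sl] = labels == (int(np.argmax(sizes)) + 1)
    return out


def corrupt_semantic(
    gt_masks: list[InstanceMask], spec: CorruptionSpec
) -> np.ndarray:
    """Semantic-segmenter corruption: merged blobs plus boundary noise.

    Each of the ``n − 1`` inter-vertebral gaps is independently bridged
    with probability ``p_merge`` by painting a connecting band between the
    facing edges, so with zero jitter the number of connected components
    is exactly ``n`` minus the number of bridged gaps.
    """
    rng = np.random.default_rng([spec.seed, 0])
    shape = gt_masks[0].shape
    raster = np.zeros(shape, dtype=bool)
    for m in gt_masks:
        raster |= m.pixels
    order = sorted(gt_masks, key=lambda m: m.centroid[0])
    for upper, lower in zip(order, order[1:]):
        if rng.random() >= spec.p_merge:
            continue
        r0, r1 = upper.bbox[1], lower.bbox[0]
        c0 = max(upper.bbox[2], lower.bbox[2])
        c1 = min(upper.bbox[3], lower.bbox[3])
        shrink = int(0.2 * (c1 - c0))
        c0, c1 = c0 + shrink, c1 - shrink
        if c0 > c1:  # pragma: no cover - neighbours always overlap laterally
            cc = int((upper.centroid[1] + lower.centroid[1]) / 2)
            c0, c1 = cc - 5, cc + 5
        raster[r0 : r1 + 1, c0 : c1 + 1] = True
    return _jitter_raster(raster, rng, spec.boundary_jitter_px)


def corrupt_instance(
    gt_masks: list[InstanceMask],
    gt_labels: list[str],
    spec: CorruptionSpec,
) -> list[InstanceMask]:
    """Instance-segmenter corruption: dropped bodies plus boundary noise.

    Each body survives with probability ``1 − p_drop``; the topmost and
    bottommost bodies — partially visible at the image edge in real
    radiographs — get a doubled drop probability.  Survivors are jittered;
    the reference body (C2/S1) keeps its class tag with a confidence drawn
    uniformly from [0.7, 1.0], all others are tagged ``vertebra``.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n = len(gt_masks)
    out: list[InstanceMask] = []
    for i, (mask, label) in enumerate(zip(gt_masks, gt_labels)):
        p = spec.p_drop * 2 if i in (0, n - 1) else spec.p_drop
        dropped = rng.random() < min(p, 1.0)
        conf = float(rng.uniform(0.7, 1.0))
        if dropped:
            continue
        raster = _jitter_raster(mask.pixels, rng, spec.boundary_jitter_px)
        raster = _largest_component(raster).copy()
        sl = _crop_slices(raster, 1)
        raster[sl] = ndimage.binary_fill_holes(raster[sl])
        tag = label if label in ("C2", "S1") else "vertebra"
        out.append(
            InstanceMask(raster, source="instance", class_tag=tag, confidence=conf)
        )
    return out


# -- convenience bundle and on-disk benchmark -------------------------------


@dataclass
class SpineCase:
    """One fully generated fixture: truth plus both corrupted sources."""

    spec: SpineSpec
    corruption: CorruptionSpec
    annotation: GroundTruthAnnotation
    gt_masks: list[InstanceMask]
    gt_labels: list[str]
    semantic: np.ndarray
    instances: list[InstanceMask]


def make_case(spec: SpineSpec, corruption: CorruptionSpec) -> SpineCase:
    """Generate ground truth and both corrupted segmentations in memory."""
    ann, masks = generate_spine(spec)
    labels = ann.labels
    return SpineCase(
        spec=spec, corruption=corruption, annotation=ann,
        gt_masks=masks, gt_labels=labels,
        semantic=corrupt_semantic(masks, corruption),
        instances=corrupt_instance(masks, labels, corruption),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def make_benchmark(
    n_spines: int,
    out_dir: str | Path,
    corruption: CorruptionSpec | None = None,
    regions: tuple[str, ...] = ("cervical", "lumbar"),
    n_range: tuple[int, int] = (5, 9),
    image_size: tuple[int, int] = (512, 256),
    seed: int = 0,
) -> dict:
    """Write ``n_spines`` fixture sets plus a checksummed manifest.

    Each fixture directory holds ``gt.json`` (landmark annotation),
    ``gt_masks/`` (one PNG per vertebra), ``semantic.png`` and
    ``instances/`` (PNGs + sidecar).  Fully reproducible from *seed*.
    """
    corruption = corruption or CorruptionSpec()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": seed, "n_spines": n_spines, "spines": []}
    for i in range(n_spines):
        region = str(rng.choice(list(regions)))
        n_vert = int(rng.integers(n_range[0], n_range[1] + 1))
        spec = SpineSpec(
            region=region, n_vertebrae=n_vert, image_size=image_size,
            seed=int(rng.integers(2**31)),
        )
        corr = CorruptionSpec(
            p_merge=corruption.p_merge, p_drop=corruption.p_drop,
            boundary_jitter_px=corruption.boundary_jitter_px,
            seed=int(rng.integers(2**31)),
        )
        case = make_case(spec, corr)
        sdir = out_dir / f"spine_{i:03d}"
        sdir.mkdir(exist_ok=True)
        save_annotation(case.annotation, sdir / "gt.json")
        gdir = sdir / "gt_masks"
        gdir.mkdir(exist_ok=True)
        for label, mask in zip(case.gt_labels, case.gt_masks):
            write_mask_png(mask, gdir / f"{label}.png")
        write_mask_png(case.semantic, sdir / "semantic.png")
        save_instance_set(case.instances, sdir / "instances")
        files = sorted(p for p in sdir.rglob("*") if p.is_file())
        manifest["spines"].append({
            "dir": sdir.name, "region": region, "n_vertebrae": n_vert,
            "spine_seed": spec.seed, "corruption_seed": corr.seed,
            "checksums": {str(p.relative_to(sdir)): _sha256(p) for p in files},
        })
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True)
    )
    logger.info("wrote %d fixtures to %s", n_spines, out_dir)
    return manifest
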