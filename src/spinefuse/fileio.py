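"""File formats, configuration, and the segmenter plug-in contract.

Everything the pipeline reads or writes is plain text or PNG:

* masks — single-channel PNG, 0 = background, 255 = foreground;
* instance sets — a directory of per-instance mask PNGs plus an
  ``instances.json`` sidecar carrying class tag and confidence;
* ground-truth annotations — JSON, one entry per vertebra with an
  anatomical label and 8 ordered (row, col) landmark points outlining the
  body, in the style of the NHANES-II landmark convention;
* labeled-spine output (``spine.json``) — per vertebra: label, area,
  centroid, traced contour polygon, provenance, plus a mask PNG; the
  evaluation stage reads this same schema back as the prediction;
* configuration — YAML with the fusion thresholds.

All JSON is written with sorted keys so identical runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
import shapely
import yaml
from PIL import Image

from .ensemble import EnsembleConfig
from .geometry import InstanceMask, MaskError, polygon_to_raster, trace_contour
from .identify import LabeledSpine
from .metrics import EvalReport

logger = logging.getLogger("spinefuse")

N_LANDMARKS = 8


class AnnotationError(ValueError):
    """Malformed ground-truth annotation file."""


# -- segmenter plug-in contract ---------------------------------------------


class SemanticSegmenter(Protocol):
    """Pluggable per-pixel backend: image raster -> binary foreground raster."""

    def __call__(self, image: np.ndarray) -> np.ndarray: ...


class InstanceSegmenter(Protocol):
    """Pluggable per-object backend: image raster -> tagged instance masks."""

    def __call__(self, image: np.ndarray) -> list[InstanceMask]: ...


# -- ground-truth annotations -----------------------------------------------


@dataclass
class GroundTruthAnnotation:
    """Per-vertebra 8-landmark outlines plus anatomical labels."""

    vertebrae: list[tuple[str, np.ndarray]]  # (label, (8, 2) row/col points)
    image_size: tuple[int, int]
    source_id: str = ""

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.vertebrae]


def _validate_polygon(label: str, pts: np.ndarray, reorder: bool) -> np.ndarray:
    pts = np.asarray(pts, dtype=float)
    if pts.shape != (N_LANDMARKS, 2):
        raise AnnotationError(
            f"vertebra {label!r}: expected {N_LANDMARKS} (row, col) landmarks, "
            f"got shape {tuple(pts.shape)}"
        )
    if reorder:
        center = pts.mean(axis=0)
        ang = np.arctan2(pts[:, 0] - center[0], pts[:, 1] - center[1])
        pts = pts[np.argsort(ang)]
    poly = shapely.Polygon(pts[:, ::-1])
    if not poly.is_valid or poly.area <= 0:
        raise AnnotationError(
            f"vertebra {label!r}: landmark polygon is degenerate or "
            "self-intersecting"
        )
    return pts


def load_annotation(path: str | Path, reorder_landmarks: bool = False) -> GroundTruthAnnotation:
    """Load and validate a ground-truth annotation JSON file.

    ``reorder_landmarks`` re-sorts each vertebra's points by angle about
    their centroid, for datasets whose landmark ordering convention is
    unknown.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"{path}: not valid JSON ({exc})") from exc
    try:
        image_size = tuple(int(v) for v in raw["image_size"])
        entries = raw["vertebrae"]
    except (KeyError, TypeError) as exc:
        raise AnnotationError(f"{path}: missing required field ({exc})") from exc
    vertebrae: list[tuple[str, np.ndarray]] = []
    seen: set[str] = set()
    for entry in entries:
        label = str(entry["label"])
        if label in seen:
            raise AnnotationError(f"{path}: duplicate label {label!r}")
        seen.add(label)
        pts = _validate_polygon(label, np.asarray(entry["landmarks"], dtype=float),
                                reorder_landmarks)
        vertebrae.append((label, pts))
    return GroundTruthAnnotation(
        vertebrae=vertebrae, image_size=image_size,
        source_id=str(raw.get("source_id", "")),
    )


def save_annotation(ann: GroundTruthAnnotation, path: str | Path) -> None:
    payload = {
        "image_size": list(ann.image_size),
        "source_id": ann.source_id,
        "vertebrae": [
            {"label": lab, "landmarks": np.asarray(pts, dtype=float).tolist()}
            for lab, pts in ann.vertebrae
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def rasterize_annotation(ann: GroundTruthAnnotation) -> list[tuple[str, InstanceMask]]:
    """Fill each landmark polygon to a mask at the annotation's resolution.

    Pixel-center point-in-polygon with boundary pixels included, so the
    rasterisation is reproducible by a brute-force point test.
    """
    out: list[tuple[str, InstanceMask]] = []
    for label, pts in ann.vertebrae:
        try:
            raster = polygon_to_raster(pts, ann.image_size)
            out.append((label, InstanceMask(raster, source="ground_truth")))
        except MaskError as exc:
            raise AnnotationError(f"vertebra {label!r}: {exc}") from exc
    return out


# -- mask and instance-set files --------------------------------------------


def write_mask_png(mask: InstanceMask | np.ndarray, path: str | Path) -> None:
    px = mask.pixels if isinstance(mask, InstanceMask) else np.asarray(mask, bool)
    Image.fromarray((px.astype(np.uint8)) * 255, mode="L").save(path)


def read_mask_raster(path: str | Path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"))
    return arr >= 128


def save_instance_set(masks: list[InstanceMask], out_dir: str | Path) -> None:
    """Write per-instance PNGs plus the ``instances.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, m in enumerate(masks):
        name = f"instance_{i:03d}.png"
        write_mask_png(m, out_dir / name)
        entry: dict = {"file": name, "class_tag": m.class_tag}
        if m.confidence is not None:
            entry["confidence"] = float(m.confidence)
        entries.append(entry)
    (out_dir / "instances.json").write_text(
        json.dumps(entries, indent=1, sort_keys=True)
    )


def load_instance_set(in_dir: str | Path) -> list[InstanceMask]:
    """Read an instance directory written by :func:`save_instance_set`."""
    in_dir = Path(in_dir)
    sidecar = in_dir / "instances.json"
    if not sidecar.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar}")
    masks = []
    for entry in json.loads(sidecar.read_text()):
        raster = read_mask_raster(in_dir / entry["file"])
        masks.append(
            InstanceMask(
                raster, source="instance",
                class_tag=entry.get("class_tag", "vertebra"),
                confidence=entry.get("confidence"),
            )
        )
    return masks


# -- labeled-spine output ---------------------------------------------------


def save_spine(spine: LabeledSpine, out_dir: str | Path) -> Path:
    """Write ``spine.json`` plus per-vertebra mask PNGs under *out_dir*."""
    out_dir = Path(out_dir)
    mask_dir = out_dir / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (mask, label) in enumerate(spine.vertebrae):
        name = f"{i:02d}_{label}.png"
        write_mask_png(mask, mask_dir / name)
        entries.append({
            "label": label,
            "mask_file": f"masks/{name}",
            "area": mask.area,
            "centroid": list(mask.centroid),
            "provenance": mask.provenance,
            "polygon": np.round(trace_contour(mask), 2).tolist(),
        })
    unl = []
    for i, mask in enumerate(spine.unlabeled):
        name = f"unlabeled_{i:02d}.png"
        write_mask_png(mask, mask_dir / name)
        unl.append({"mask_file": f"masks/{name}", "area": mask.area,
                    "centroid": list(mask.centroid),
                    "provenance": mask.provenance})
    payload = {
        "reference": spine.reference,
        "direction": spine.direction,
        "vertebrae": entries,
        "unlabeled": unl,
    }
    if spine.ensemble is not None:
        payload["ensemble"] = {
            "counts": spine.ensemble.counts,
            "mu_area": spine.ensemble.mu_area,
            "sigma_area": spine.ensemble.sigma_area,
        }
    path = out_dir / "spine.json"
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def load_spine(path: str | Path) -> LabeledSpine:
    """Read a ``spine.json`` (with its mask PNGs) back into a LabeledSpine."""
    path = Path(path)
    raw = json.loads(path.read_text())
    base = path.parent
    vertebrae = []
    for entry in raw["vertebrae"]:
        raster = read_mask_raster(base / entry["mask_file"])
        mask = InstanceMask(raster, source="ensemble",
                            provenance=entry.get("provenance", "raw"))
        vertebrae.append((mask, entry["label"]))
    unlabeled = [
        InstanceMask(read_mask_raster(base / e["mask_file"]), source="ensemble",
                     provenance=e.get("provenance", "raw"))
        for e in raw.get("unlabeled", [])
    ]
    return LabeledSpine(
        vertebrae=vertebrae, reference=raw.get("reference", "none"),
        direction=raw.get("direction", "none"), unlabeled=unlabeled,
    )


def save_report(reports: dict[float, EvalReport], path: str | Path) -> None:
    payload = {f"{thr:g}": rep.as_dict() for thr, rep in reports.items()}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# -- configuration ----------------------------------------------------------


def load_config(path: str | Path | None) -> EnsembleConfig:
    """Build an :class:`EnsembleConfig` from a YAML file (``None`` -> defaults)."""
    if path is None:
        return EnsembleConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    allowed = {"eta", "lam", "pickup_dedup_iou", "min_area_px"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return EnsembleConfig(**raw)
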