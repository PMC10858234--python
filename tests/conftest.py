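"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorised code paths: areas
and intersections are counted with explicit Python loops, and
point-in-polygon uses a scalar ray test, so they can certify the geometry
kernels rather than mirror them.
"""

from __future__ import annotations

import numpy as np
import pytest

from spinefuse import InstanceMask


# -- mask builders ----------------------------------------------------------


def rect_mask(shape, r0, r1, c0, c1, **kw) -> InstanceMask:
    """Axis-aligned filled rectangle, rows r0..r1-1, cols c0..c1-1."""
    px = np.zeros(shape, dtype=bool)
    px[r0:r1, c0:c1] = True
    return InstanceMask(px, **kw)


def coords_mask(shape, coords, **kw) -> InstanceMask:
    px = np.zeros(shape, dtype=bool)
    for r, c in coords:
        px[r, c] = True
    return InstanceMask(px, **kw)


def random_blob(rng: np.random.Generator, shape=(24, 24)) -> InstanceMask:
    """Random single-component blob: a filled rectangle with noisy edges."""
    H, W = shape
    r0 = int(rng.integers(0, H - 6))
    c0 = int(rng.integers(0, W - 6))
    h = int(rng.integers(3, min(10, H - r0)))
    w = int(rng.integers(3, min(10, W - c0)))
    px = np.zeros(shape, dtype=bool)
    px[r0 : r0 + h, c0 : c0 + w] = True
    edge = px & ~np.roll(px, 1, axis=0)  # nibble the top edge
    px ^= edge & (rng.random(shape) < 0.3)
    if not px.any():
        px[r0 + h // 2, c0 + w // 2] = True
    from scipy import ndimage

    labels, n = ndimage.label(px, structure=np.ones((3, 3), bool))
    if n > 1:
        sizes = [(labels == i).sum() for i in range(1, n + 1)]
        px = labels == (int(np.argmax(sizes)) + 1)
    return InstanceMask(px)


# -- brute-force oracles ----------------------------------------------------


def naive_area(mask: InstanceMask) -> int:
    count = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask.pixels[r, c]:
                count += 1
    return count


def naive_intersection(a: InstanceMask, b: InstanceMask) -> int:
    count = 0
    for r in range(a.shape[0]):
        for c in range(a.shape[1]):
            if a.pixels[r, c] and b.pixels[r, c]:
                count += 1
    return count


def naive_point_in_polygon(point_rc, polygon_rc) -> bool:
    """Scalar even-odd ray test, boundary counted as inside."""
    py, px_ = float(point_rc[0]), float(point_rc[1])
    pts = [(float(r), float(c)) for r, c in polygon_rc]
    n = len(pts)
    inside = False
    for i in range(n):
        r1, c1 = pts[i]
        r2, c2 = pts[(i + 1) % n]
        # on-segment check
        cross = (r2 - r1) * (px_ - c1) - (c2 - c1) * (py - r1)
        if abs(cross) < 1e-9:
            if min(r1, r2) - 1e-9 <= py <= max(r1, r2) + 1e-9 and \
               min(c1, c2) - 1e-9 <= px_ <= max(c1, c2) + 1e-9:
                return True
        if (r1 > py) != (r2 > py):
            x_at = c1 + (py - r1) * (c2 - c1) / (r2 - r1)
            if px_ < x_at:
                inside = not inside
    return inside


# -- fixtures ---------------------------------------------------------------


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260924)
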