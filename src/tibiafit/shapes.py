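"""Shared planar shape family and polygon utilities.

Both the synthetic resection cross-section and the implant footprint library
are built from the same base outline: an ellipse (medial-lateral semi-axis
``aspect`` times the antero-posterior one) that narrows posteriorly by a
``taper`` fraction and is flattened anteriorly by a straight chord covering
``flat_fraction`` of the half-width — the anterior cortical flat of the
distal tibia and, congruently, the straight ventral shield of the tray.

Coordinates are (u, v) in mm with +u medial and +v anterior.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "base_outline",
    "polygon_area",
    "resample_closed",
    "ensure_ccw",
]


def base_outline(
    n: int,
    aspect: float = 1.35,
    taper: float = 0.25,
    flat_fraction: float = 0.45,
) -> np.ndarray:
    """Evaluate the base outline on ``n`` uniform parameter values.

    Returns an (n, 2) open polygon (last point != first) of unit scale:
    the underlying ellipse has unit area before tapering/flattening.
    theta = 0 points medial (+u), theta = pi/2 anterior (+v).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    # unit-area ellipse: pi*a*b = 1 with a = aspect*b
    b = 1.0 / np.sqrt(np.pi * aspect)
    a = aspect * b
    u = a * np.cos(theta)
    v = b * np.sin(theta)
    # posterior taper: shrink |u| linearly from 1 at v=+b to (1-taper) at v=-b
    width = 1.0 - taper * (b - v) / (2.0 * b)
    u = u * width
    # anterior flat: clip v to the ellipse height at |u| = flat_fraction*a
    if flat_fraction > 0.0:
        v_cut = b * np.sqrt(max(1.0 - flat_fraction**2, 0.0))
        v = np.minimum(v, v_cut)
    return np.column_stack([u, v])


def polygon_area(points: np.ndarray) -> float:
    """Signed shoelace area of a closed polygon given as open vertex list."""
    u = np.asarray(points)[:, 0]
    v = np.asarray(points)[:, 1]
    return 0.5 * float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the polygon with counter-clockwise (positive-area) orientation."""
    if polygon_area(points) < 0.0:
        return points[::-1].copy()
    return points


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to ``n`` points equally spaced in arc length.

    The first output point coincides with the first input point, so the
    parameterization origin is preserved.
    """
    pts = np.asarray(points, dtype=float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise ValueError("degenerate polygon with zero perimeter")
    targets = np.linspace(0.0, total, n, endpoint=False)
    u = np.interp(targets, s, closed[:, 0])
    v = np.interp(targets, s, closed[:, 1])
    return np.column_stack([u, v])
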