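"""Closed-contour geometry primitives.

A contour is an ``(N, 2)`` float array of ``(x, y)`` vertices describing a
simple closed polygon.  The last vertex is implicitly joined to the first
(no repeated endpoint).  ``x`` is the image column, ``y`` the row, origin at
the top-left pixel; the positive-orientation (counter-clockwise) convention
is signed shoelace area > 0 in these coordinates.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "as_contour",
    "signed_area",
    "ensure_ccw",
    "centroid",
    "perimeter",
    "resample",
    "transform",
    "is_convex",
    "radius_profile",
]


def as_contour(points) -> np.ndarray:
    """Validate and return a contour as an (N, 2) float array.

    Drops a duplicated closing vertex if present.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError(f"contour must be (N, 2), got {pts.shape}")
    if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 3:
        raise ValueError("contour needs at least 3 distinct vertices")
    if not np.all(np.isfinite(pts)):
        raise ValueError("contour contains non-finite coordinates")
    return pts


def signed_area(pts: np.ndarray) -> float:
    """Shoelace signed area; positive for CCW orientation."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


def ensure_ccw(pts: np.ndarray) -> np.ndarray:
    pts = as_contour(pts)
    if signed_area(pts) < 0:
        pts = pts[::-1].copy()
    return pts


def centroid(pts: np.ndarray) -> np.ndarray:
    """Area centroid of the enclosed polygon."""
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    if a == 0:
        raise ValueError("degenerate (zero-area) contour")
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


def perimeter(pts: np.ndarray) -> float:
    d = np.roll(pts, -1, axis=0) - pts
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def resample(pts: np.ndarray, n: int) -> np.ndarray:
    """Resample the closed polyline to ``n`` equally spaced arc-length points.

    The first output point coincides with the first input vertex, so
    similarity transforms commute exactly with resampling.
    """
    pts = as_contour(pts)
    closed = np.vstack([pts, pts[:1]])
    seg = np.diff(closed, axis=0)
    s = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate contour with zero perimeter")
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def transform(
    pts: np.ndarray,
    *,
    scale: float | tuple[float, float] = 1.0,
    rotation: float = 0.0,
    translation=(0.0, 0.0),
    skew: float = 0.0,
) -> np.ndarray:
    """Affine map: skew, then (an)isotropic scale, then rotation, then shift."""
    sx, sy = (scale, scale) if np.isscalar(scale) else scale
    k = np.array([[1.0, skew], [0.0, 1.0]])
    s = np.array([[sx, 0.0], [0.0, sy]])
    c, sn = np.cos(rotation), np.sin(rotation)
    r = np.array([[c, -sn], [sn, c]])
    return pts @ (r @ s @ k).T + np.asarray(translation, dtype=float)


def is_convex(pts: np.ndarray, tol: float = 1e-9) -> bool:
    """True if every cross product of consecutive edges has the same sign."""
    d = np.roll(pts, -1, axis=0) - pts
    cross = d[:, 0] * np.roll(d[:, 1], -1) - d[:, 1] * np.roll(d[:, 0], -1)
    scale = np.max(np.abs(cross)) or 1.0
    cross = cross / scale
    return bool(np.all(cross > -tol) or np.all(cross < tol))


def radius_profile(pts: np.ndarray, n_theta: int, dense: int = 2048) -> np.ndarray:
    """Centroid-to-boundary radius sampled at ``n_theta`` uniform angles.

    Valid for shapes star-shaped about their centroid (all convex shapes).
    Angle 0 is the +x direction, increasing towards +y.
    """
    c = centroid(pts)
    d = resample(pts, dense) - c
    theta = np.arctan2(d[:, 1], d[:, 0])
    r = np.hypot(d[:, 0], d[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    # periodic padding for interpolation across the -pi/pi seam
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    grid = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    return np.interp(grid, theta_ext, r_ext)
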