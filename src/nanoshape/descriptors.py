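"""Per-contour shape descriptors.

The shape of a particle contour is summarised by the (logarithms of the)
Hu moment invariants and by the pair of shape eigenvalues ``(eta1, eta2)``
derived from them.  The eigenvalues are scaled so that for an ellipse whose
contour encloses unit area they equal its semi-major and semi-minor axes;
their ratio is the particle aspect ratio, and the curve
``eta2 = 1 / (pi * eta1)`` is the locus of all perfect ellipses.

All moments are computed in closed form from the polygon vertices via
Green's theorem, so the descriptors are resolution-independent: contours
are resampled to at least 256 equal arc-length points first, and the Hu
invariants are stable under similarity transforms to ~1e-4 relative error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contours import as_contour, resample, signed_area

__all__ = [
    "ShapeDescriptor",
    "polygon_moments",
    "hu_features",
    "shape_eigenvalues",
    "effective_diameter",
    "principal_orientation",
    "describe",
    "describe_all",
    "descriptor_table",
]

#: additive floor inside the log so circularly symmetric shapes (H2 = 0)
#: keep a finite feature value
LOG_EPS = 1e-12

#: H2 below this is treated as "no preferred orientation"
ISOTROPY_FLOOR = 1e-10

_MIN_POINTS = 256


@dataclass
class PolygonMoments:
    """Raw (m) and central (mu) polygon moments up to order 3."""

    m00: float
    centroid: tuple[float, float]
    mu: dict[tuple[int, int], float]


@dataclass
class ShapeDescriptor:
    """Shape and size summary of one particle contour."""

    H: np.ndarray
    logH: np.ndarray
    eta1: float
    eta2: float
    area_px: float
    effective_diameter: float
    aspect_ratio: float
    orientation: float
    isotropic: bool
    centroid: tuple[float, float]
    extras: dict = field(default_factory=dict)


def polygon_moments(contour, max_order: int = 3) -> PolygonMoments:
    """Exact area moments of the polygon enclosed by ``contour``.

    Uses the closed-form Green's-theorem line integrals over the vertex
    list; no rasterization is involved.  The contour must be simple and
    counter-clockwise (m00 > 0).
    """
    pts = as_contour(contour)
    x, y = pts[:, 0], pts[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    w = x * yn - xn * y  # per-edge cross terms

    m00 = np.sum(w) / 2.0
    if m00 <= 0:
        if m00 == 0:
            raise ValueError("degenerate (zero-area) contour")
        raise ValueError("contour must be counter-clockwise (signed area > 0)")

    m10 = np.sum((x + xn) * w) / 6.0
    m01 = np.sum((y + yn) * w) / 6.0
    cx, cy = m10 / m00, m01 / m00

    # shift to the centroid first: the integrals below then give central
    # moments directly, which is better conditioned than the raw-moment
    # recurrences for far-from-origin contours
    u, v = x - cx, y - cy
    un, vn = np.roll(u, -1), np.roll(v, -1)
    w = u * vn - un * v

    mu = {(0, 0): float(m00), (1, 0): 0.0, (0, 1): 0.0}
    if max_order >= 2:
        mu[(2, 0)] = float(np.sum((u * u + u * un + un * un) * w) / 12.0)
        mu[(0, 2)] = float(np.sum((v * v + v * vn + vn * vn) * w) / 12.0)
        mu[(1, 1)] = float(
            np.sum((2 * u * v + u * vn + un * v + 2 * un * vn) * w) / 24.0
        )
    if max_order >= 3:
        mu[(3, 0)] = float(
            np.sum((u**3 + u**2 * un + u * un**2 + un**3) * w) / 20.0
        )
        mu[(0, 3)] = float(
            np.sum((v**3 + v**2 * vn + v * vn**2 + vn**3) * w) / 20.0
        )
        mu[(2, 1)] = float(
            np.sum(
                (
                    3 * u**2 * v
                    + 2 * u * un * v
                    + un**2 * v
                    + u**2 * vn
                    + 2 * u * un * vn
                    + 3 * un**2 * vn
                )
                * w
            )
            / 60.0
        )
        mu[(1, 2)] = float(
            np.sum(
                (
                    3 * v**2 * u
                    + 2 * v * vn * u
                    + vn**2 * u
                    + v**2 * un
                    + 2 * v * vn * un
                    + 3 * vn**2 * un
                )
                * w
            )
            / 60.0
        )
    return PolygonMoments(m00=float(m00), centroid=(float(cx), float(cy)), mu=mu)


def _normalized_moments(mom: PolygonMoments) -> dict[tuple[int, int], float]:
    """Scale-invariant normalized central moments nu_pq = mu_pq / m00^(1+(p+q)/2)."""
    nu = {}
    for (p, q), val in mom.mu.items():
        if p + q < 2:
            continue
        nu[(p, q)] = val / mom.m00 ** (1 + (p + q) / 2.0)
    return nu


def _hu_invariants(nu: dict[tuple[int, int], float], n_hu: int) -> np.ndarray:
    n20, n02, n11 = nu[(2, 0)], nu[(0, 2)], nu[(1, 1)]
    hu = [n20 + n02, (n20 - n02) ** 2 + 4 * n11**2]
    if n_hu > 2:
        n30, n03 = nu[(3, 0)], nu[(0, 3)]
        n21, n12 = nu[(2, 1)], nu[(1, 2)]
        a, b = n30 - 3 * n12, 3 * n21 - n03
        c, d = n30 + n12, n21 + n03
        hu += [
            a**2 + b**2,
            c**2 + d**2,
            a * c * (c**2 - 3 * d**2) + b * d * (3 * c**2 - d**2),
            (n20 - n02) * (c**2 - d**2) + 4 * n11 * c * d,
            b * c * (c**2 - 3 * d**2) - a * d * (3 * c**2 - d**2),
        ]
    return np.array(hu[:n_hu])


def hu_features(contour, n_hu: int = 2, n_points: int = _MIN_POINTS):
    """Hu invariants ``H`` of a contour and their log10 feature vector.

    Only ``H1, H2`` are used for classification by default; the higher
    invariants (up to 7) are available for more complex shape families.
    """
    if not 2 <= n_hu <= 7:
        raise ValueError("n_hu must be in 2..7")
    pts = resample(as_contour(contour), max(n_points, _MIN_POINTS))
    if signed_area(pts) < 0:
        pts = pts[::-1]
    mom = polygon_moments(pts, max_order=3 if n_hu > 2 else 2)
    hu = _hu_invariants(_normalized_moments(mom), n_hu)
    logh = np.log10(np.abs(hu) + LOG_EPS)
    return hu, logh, mom


def shape_eigenvalues(h1: float, h2: float) -> tuple[float, float]:
    """Shape eigenvalues (eta1 >= eta2) from the first two Hu invariants.

    ``lam_{1,2} = (H1 +/- sqrt(H2)) / 2`` are the eigenvalues of the inertia
    tensor of the unit-area shape; the returned ``eta_{1,2} = 2 sqrt(lam)``
    are scaled so a unit-area ellipse yields exactly its semi-axes (a
    unit-area circle gives eta1 = eta2 = 1/sqrt(pi), its radius).
    """
    if h1 <= 0:
        raise ValueError("H1 must be positive")
    h2 = max(h2, 0.0)
    if h1 * h1 < h2 * (1 - 1e-12):
        raise ValueError("H1^2 < H2: not realizable by any shape")
    root = np.sqrt(min(h2, h1 * h1))
    lam1, lam2 = (h1 + root) / 2.0, (h1 - root) / 2.0
    return 2.0 * np.sqrt(lam1), 2.0 * np.sqrt(lam2)


def effective_diameter(area_px: float, pixel_size: float) -> float:
    """Equal-area-circle diameter in physical units (nm)."""
    if area_px <= 0:
        raise ValueError("area must be positive")
    return 2.0 * np.sqrt(area_px / np.pi) * pixel_size


def principal_orientation(contour, h2_floor: float = ISOTROPY_FLOOR):
    """Major-principal-axis angle in (-pi/2, pi/2] and an isotropy flag.

    Shapes with H2 below ``h2_floor`` (e.g. circles, regular polygons) have
    no preferred axis; they report angle 0 with ``isotropic=True``.
    """
    hu, _, mom = hu_features(contour, n_hu=2)
    if hu[1] < h2_floor:
        return 0.0, True
    mu = mom.mu
    theta = 0.5 * np.arctan2(2.0 * mu[(1, 1)], mu[(2, 0)] - mu[(0, 2)])
    if theta <= -np.pi / 2:
        theta += np.pi
    elif theta > np.pi / 2:
        theta -= np.pi
    return float(theta), False


def describe(contour, pixel_size: float = 1.0, n_hu: int = 2) -> ShapeDescriptor:
    """Full descriptor set for one contour."""
    hu, logh, mom = hu_features(contour, n_hu=n_hu)
    eta1, eta2 = shape_eigenvalues(hu[0], hu[1])
    theta, iso = principal_orientation(contour)
    return ShapeDescriptor(
        H=hu,
        logH=logh,
        eta1=float(eta1),
        eta2=float(eta2),
        area_px=mom.m00,
        effective_diameter=effective_diameter(mom.m00, pixel_size),
        aspect_ratio=float(eta1 / eta2) if eta2 > 0 else np.inf,
        orientation=theta,
        isotropic=iso,
        centroid=mom.centroid,
    )


def describe_all(contours, pixel_size: float = 1.0, n_hu: int = 2):
    return [describe(c, pixel_size=pixel_size, n_hu=n_hu) for c in contours]


def descriptor_table(descriptors) -> pd.DataFrame:
    """Tabulate descriptors, one row per particle."""
    rows = []
    for i, d in enumerate(descriptors):
        row = {
            "particle_id": i,
            "area_px": d.area_px,
            "d_eff_nm": d.effective_diameter,
            "eta1": d.eta1,
            "eta2": d.eta2,
            "AR": d.aspect_ratio,
            "orientation": d.orientation,
            "isotropic": d.isotropic,
            "centroid_x": d.centroid[0],
            "centroid_y": d.centroid[1],
        }
        for j, (h, lh) in enumerate(zip(d.H, d.logH), start=1):
            row[f"H{j}"] = h
            row[f"logH{j}"] = lh
        rows.append(row)
    return pd.DataFrame(rows)
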