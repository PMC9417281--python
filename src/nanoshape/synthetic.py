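"""Synthetic micrograph scenes with known ground truth.

No public micrograph data accompanies the method, so this module generates
the scenes every downstream stage is tested against: convex particle
contours from a handful of shape families, rendered with a projected
thickness-like dome contrast on configurable backgrounds, in either
bright-field or dark-field polarity.  Three canned scenarios mirror the
situations the method targets — well-dispersed distinct shapes (hexagonal
platelets plus rods), densely packed rounded shapes on a fluctuating
background, and bright-on-dark cube-like particles with core--shell
internal contrast — plus scenes of touching, connected and aggregated
particle groups for the curvature-sign separation stage.

Sizes follow the equal-area-circle convention: the ``size`` of a particle
is the diameter of the circle with the same area as its contour, so
generator truth is directly comparable with the measured effective
diameter.  All randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon as ShapelyPolygon
from skimage.draw import polygon as draw_polygon

from .contours import centroid, ensure_ccw, is_convex, resample, signed_area, transform
from .image import GrayImage

__all__ = [
    "SHAPE_FAMILIES",
    "ClassSpec",
    "SyntheticScene",
    "make_contour",
    "render_scene",
    "make_ensemble",
    "make_aggregate_scene",
    "dispersed_hexrod_spec",
    "packed_qd_spec",
    "nanocube_spec",
]

SHAPE_FAMILIES = ("hexagon", "rod", "ellipse", "rounded_cube", "polygon")

# default corner rounding per family (fraction of the base-shape inradius);
# free parameters of the generator, not calibrated to any measured sample
_DEFAULT_ROUNDING = {
    "hexagon": 0.15,
    "rod": 0.85,
    "ellipse": 0.0,
    "rounded_cube": 0.35,
    "polygon": 0.1,
}


@dataclass
class ClassSpec:
    """Per-class recipe for :func:`make_ensemble`."""

    label: str
    family: str
    count: int
    size_nm: float
    size_sd_nm: float = 0.0
    aspect_ratio: float = 1.0
    ar_sd: float = 0.0
    ar_min: float = 1.0
    corner_rounding: float | None = None
    rounding_sd: float = 0.0  # per-particle corner-rounding jitter
    n_sides: int = 5


@dataclass
class SyntheticScene:
    """Rendered image (optional) plus per-particle ground truth."""

    image: GrayImage | None
    truth_contours: list
    truth_labels: list
    truth_params: pd.DataFrame
    seed: int | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.truth_contours) != len(self.truth_labels):
            raise ValueError("contours/labels length mismatch")
        if len(self.truth_params) != len(self.truth_contours):
            raise ValueError("truth table length mismatch")


def _base_polygon(family: str, n_sides: int) -> np.ndarray:
    """Symmetric unit base shape (isotropic inertia tensor) per family."""
    if family == "hexagon":
        n = 6
    elif family in ("rod", "rounded_cube"):
        n = 4
    elif family == "polygon":
        n = int(n_sides)
        if n < 3:
            raise ValueError("polygon needs at least 3 sides")
    elif family == "ellipse":
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        return np.column_stack([np.cos(t), np.sin(t)])
    else:
        raise ValueError(f"unknown shape family {family!r}")
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([np.cos(t), np.sin(t)])


def _round_corners(poly: np.ndarray, fraction: float) -> np.ndarray:
    """Replace corners with circular arcs of radius fraction * inradius."""
    if fraction <= 0:
        return poly
    fraction = min(fraction, 0.95)
    shp = ShapelyPolygon(poly)
    c = centroid(poly)
    # inradius = min perpendicular distance from centroid to an edge
    edges = np.roll(poly, -1, axis=0) - poly
    rel = c - poly
    cross = np.abs(edges[:, 0] * rel[:, 1] - edges[:, 1] * rel[:, 0])
    inr = float(np.min(cross / np.hypot(edges[:, 0], edges[:, 1])))
    r = fraction * inr
    rounded = shp.buffer(-r, join_style="mitre").buffer(r, quad_segs=32)
    return np.asarray(rounded.exterior.coords)[:-1]


def make_contour(
    shape_family: str,
    size: float,
    aspect_ratio: float = 1.0,
    corner_rounding: float | None = None,
    orientation: float = 0.0,
    rng: np.random.Generator | int | None = None,
    irregularity: float = 0.0,
    n_points: int = 256,
    n_sides: int = 5,
    convex_only: bool = True,
) -> np.ndarray:
    """Generate one closed, convex, CCW particle contour.

    ``size`` is the equal-area-circle diameter (the enclosed area is
    ``pi * (size/2)**2`` exactly, by construction).  Anisotropy is applied
    as an area-preserving stretch of a symmetric base shape, which makes
    the descriptor-measured aspect ratio (eta1/eta2) equal the requested
    ``aspect_ratio`` exactly for every family.  ``irregularity`` adds a
    smooth random radial perturbation (fractional sd) for non-ideal shapes.
    """
    if shape_family not in SHAPE_FAMILIES:
        raise ValueError(f"unknown shape family {shape_family!r}")
    if size <= 0:
        raise ValueError("size must be positive")
    if aspect_ratio < 1:
        raise ValueError("aspect_ratio must be >= 1")
    if corner_rounding is None:
        corner_rounding = _DEFAULT_ROUNDING[shape_family]
    if not 0 <= corner_rounding <= 1:
        raise ValueError("corner_rounding must be in [0, 1]")

    base = _base_polygon(shape_family, n_sides)
    if shape_family != "ellipse":
        base = _round_corners(base, corner_rounding)
    pts = resample(ensure_ccw(base), n_points)

    if irregularity > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        # band-limited radial noise: a few low harmonics only, so the
        # perturbed shape stays smooth and (for small amplitude) convex
        n_harm = 6
        amps = gen.normal(0, irregularity, n_harm)
        phases = gen.uniform(0, 2 * np.pi, n_harm)
        ang = np.arctan2(pts[:, 1], pts[:, 0])
        pert = sum(
            a * np.cos((k + 2) * ang + p)
            for k, (a, p) in enumerate(zip(amps, phases))
        )
        pts = pts * (1.0 + pert)[:, None]

    t = np.sqrt(aspect_ratio)
    pts = transform(pts, scale=(t, 1.0 / t), rotation=orientation)
    area = signed_area(pts)
    target = np.pi * (size / 2.0) ** 2
    pts = pts * np.sqrt(target / area)
    pts -= centroid(pts)

    if convex_only and not is_convex(pts, tol=1e-6):
        raise ValueError(
            "generated contour is non-convex; lower irregularity or pass "
            "convex_only=False"
        )
    return pts


def _thickness_dome(mask: np.ndarray, edge_width: float = 0.8,
                    curvature: float = 0.3) -> np.ndarray:
    """Thickness-like profile over a filled mask.

    A steep ``tanh`` rise of width ``edge_width`` px keeps the
    half-amplitude crossing at the true particle edge (so thresholding
    recovers the contour accurately), while the ``curvature`` * sqrt term
    gives the interior the concave, dome-like profile of projected
    thickness, so the intensity Laplacian has a definite sign inside.
    """
    dt = ndimage.distance_transform_edt(mask)
    peak = dt.max()
    if peak == 0:
        return dt.astype(float)
    return (np.tanh(dt / edge_width) + curvature * np.sqrt(dt / peak)) / (1 + curvature)


def _background_field(
    shape, background: str, rng: np.random.Generator, level: float, amplitude: float
) -> np.ndarray:
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    u, v = xx / max(w - 1, 1) - 0.5, yy / max(h - 1, 1) - 0.5
    if background == "constant":
        return np.full(shape, level)
    if background == "gradient":
        return level + amplitude * (u + 0.5 * v)
    if background == "fluctuating":
        # low-order 2-D polynomial drift plus band-limited noise
        coef = rng.normal(0, 1, 6)
        poly = (
            coef[0] * u
            + coef[1] * v
            + coef[2] * u * v
            + coef[3] * (u**2 - 1 / 12)
            + coef[4] * (v**2 - 1 / 12)
            + coef[5] * u * v * (u + v)
        )
        smooth = ndimage.gaussian_filter(rng.normal(0, 1, shape), sigma=min(h, w) / 16)
        smooth /= max(np.abs(smooth).max(), 1e-12)
        poly /= max(np.abs(poly).max(), 1e-12)
        return level + amplitude * (0.6 * poly + 0.4 * smooth)
    raise ValueError(f"unknown background model {background!r}")


def render_scene(
    contours,
    image_shape=(512, 512),
    modality: str = "bright_field",
    contrast: float = 0.4,
    background: str = "constant",
    background_level: float | None = None,
    background_amplitude: float = 0.08,
    noise_sd: float = 0.0,
    edge_sigma: float = 1.0,
    fringe: float = 0.35,
    pixel_size: float = 1.0,
    rng: np.random.Generator | int | None = None,
    labels=None,
    truth_params: pd.DataFrame | None = None,
    allow_overlap: bool = False,
    allow_border: bool = False,
    core_shell: bool = False,
    seed: int | None = None,
) -> SyntheticScene:
    """Render contours into a micrograph-like image, keeping ground truth.

    Particle contrast is a dome (thickness-like) profile, so interiors are
    smooth and the intensity curvature near edges has a definite sign — the
    property the curvature-sign (binary DoG) separation stage relies on.
    Bright-field renders particles darker than the background, dark-field
    brighter.  ``core_shell`` superimposes a brighter central core on each
    particle (dark-field core--shell contrast).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if isinstance(rng, np.random.Generator):
        gen = rng
    else:
        seed = seed if seed is not None else (rng if rng is not None else 0)
        gen = np.random.default_rng(seed)
    h, w = image_shape
    contours = [ensure_ccw(c) for c in contours]

    thickness = np.zeros(image_shape)
    occupancy = np.zeros(image_shape, dtype=np.int32)
    clipped = []
    for c in contours:
        inside = (
            c[:, 0].min() >= 0 and c[:, 1].min() >= 0
            and c[:, 0].max() <= w - 1 and c[:, 1].max() <= h - 1
        )
        clipped.append(not inside)
        if not inside and not allow_border:
            raise ValueError(
                "contour extends beyond the image; pass allow_border=True to "
                "render border-clipped particles"
            )
        rr, cc = draw_polygon(c[:, 1], c[:, 0], shape=image_shape)
        mask = np.zeros(image_shape, bool)
        mask[rr, cc] = True
        occupancy += mask
        dome = _thickness_dome(mask)
        if core_shell:
            dome = dome + 0.8 * np.clip(dome - 0.55, 0, None)
        thickness += dome
        if fringe > 0:
            # faint Fresnel-like fringe just outside the edge: same contrast
            # sign as the particle, so the curvature-sign region extends
            # slightly past the contour as in slightly defocused TEM
            d_out = ndimage.distance_transform_edt(~mask)
            thickness += fringe * np.exp(-(((d_out - 0.8) / 1.2) ** 2)) * ~mask
    if not allow_overlap and occupancy.max() > 1:
        raise ValueError(
            "contours overlap; pass allow_overlap=True for aggregate scenes"
        )
    thickness = ndimage.gaussian_filter(thickness, edge_sigma)

    if background_level is None:
        background_level = 0.75 if modality == "bright_field" else 0.25
    bg = _background_field(image_shape, background, gen, background_level,
                           background_amplitude)
    sign = -1.0 if modality == "bright_field" else 1.0
    img = bg + sign * contrast * thickness
    if noise_sd > 0:
        img = img + gen.normal(0.0, noise_sd, image_shape)

    if labels is None:
        labels = ["particle"] * len(contours)
    if truth_params is None:
        cents = [centroid(c) for c in contours]
        truth_params = pd.DataFrame(
            {
                "particle_id": range(len(contours)),
                "label": list(labels),
                "cx": [c[0] for c in cents],
                "cy": [c[1] for c in cents],
            }
        )
    truth_params = truth_params.copy()
    truth_params["border_clipped"] = clipped
    return SyntheticScene(
        image=GrayImage(img, pixel_size=pixel_size, modality=modality),
        truth_contours=contours,
        truth_labels=list(labels),
        truth_params=truth_params,
        seed=seed,
    )


def _sample_particles(classes, gen, pixel_size):
    """Draw per-particle truth parameters and centered contours (px units)."""
    rows, contours, labels = [], [], []
    for spec in classes:
        if spec.count < 1:
            raise ValueError("class count must be >= 1")
        for _ in range(spec.count):
            size = spec.size_nm if spec.size_sd_nm == 0 else float(
                np.clip(gen.normal(spec.size_nm, spec.size_sd_nm),
                        0.2 * spec.size_nm, None)
            )
            if spec.ar_sd == 0:
                ar = spec.aspect_ratio
            else:
                ar = float(gen.normal(spec.aspect_ratio, spec.ar_sd))
                while ar < spec.ar_min:  # truncate at the physical floor
                    ar = float(gen.normal(spec.aspect_ratio, spec.ar_sd))
            theta = float(gen.uniform(-np.pi, np.pi))
            rounding = spec.corner_rounding
            if spec.rounding_sd > 0:
                base = (
                    rounding
                    if rounding is not None
                    else _DEFAULT_ROUNDING[spec.family]
                )
                rounding = float(
                    np.clip(gen.normal(base, spec.rounding_sd), 0.0, 0.95)
                )
            c = make_contour(
                spec.family,
                size / pixel_size,
                aspect_ratio=ar,
                corner_rounding=rounding,
                orientation=theta,
                n_sides=spec.n_sides,
            )
            contours.append(c)
            labels.append(spec.label)
            rows.append(
                {
                    "label": spec.label,
                    "family": spec.family,
                    "size_nm": size,
                    "aspect_ratio": ar,
                    "orientation": theta,
                }
            )
    return rows, contours, labels


def make_ensemble(
    classes,
    image_shape=(1024, 1024),
    pixel_size: float = 1.0,
    modality: str = "bright_field",
    seed: int = 0,
    noise_sd: float = 0.02,
    background: str = "constant",
    background_amplitude: float = 0.08,
    margin: float = 4.0,
    max_tries: int = 2000,
    render: bool = True,
    core_shell: bool = False,
    **render_kw,
) -> SyntheticScene:
    """Scene of disjoint particles drawn from per-class recipes.

    Particles are placed by rejection sampling on bounding circles, so all
    truth contours are disjoint and inside the border.  With
    ``render=False`` only contours and the truth table are produced (for
    feature-space tests that need no imaging step).
    """
    gen = np.random.default_rng(seed)
    rows, contours, labels = _sample_particles(classes, gen, pixel_size)
    h, w = image_shape

    radii = [np.max(np.hypot(c[:, 0], c[:, 1])) for c in contours]
    placed = []
    for i, (c, r) in enumerate(zip(contours, radii)):
        ok = False
        for _ in range(max_tries):
            cx = gen.uniform(r + margin, w - 1 - r - margin)
            cy = gen.uniform(r + margin, h - 1 - r - margin)
            if all(
                np.hypot(cx - px, cy - py) > r + pr + margin
                for (px, py, pr) in placed
            ):
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place all particles; enlarge image_shape or "
                "reduce counts/sizes"
            )
        placed.append((cx, cy, r))
        contours[i] = c + np.array([cx, cy])
        rows[i]["cx"], rows[i]["cy"] = cx, cy

    truth = pd.DataFrame(rows)
    truth.insert(0, "particle_id", range(len(truth)))
    if not render:
        truth["border_clipped"] = False
        return SyntheticScene(None, contours, labels, truth, seed=seed)
    return render_scene(
        contours,
        image_shape=image_shape,
        modality=modality,
        noise_sd=noise_sd,
        background=background,
        background_amplitude=background_amplitude,
        pixel_size=pixel_size,
        rng=gen,
        labels=labels,
        truth_params=truth,
        seed=seed,
        core_shell=core_shell,
        **render_kw,
    )


def _place_against(existing_polys, contour, anchor_xy, angle, overlap_fraction, gen):
    """Slide ``contour`` along ``angle`` towards ``anchor_xy`` until it
    touches (overlap_fraction=0) or slightly overlaps the existing group."""
    group = existing_polys[0]
    for p in existing_polys[1:]:
        group = group.union(p)
    u = np.array([np.cos(angle), np.sin(angle)])
    r_new = np.max(np.hypot(contour[:, 0], contour[:, 1]))
    far = group.bounds
    d_far = np.hypot(far[2] - far[0], far[3] - far[1]) + 2 * r_new
    lo, hi = 0.0, d_far  # lo: overlapping, hi: separate
    anchor = np.asarray(anchor_xy)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        poly = ShapelyPolygon(contour + anchor + mid * u)
        if poly.intersects(group):
            lo = mid
        else:
            hi = mid
    d_touch = hi
    d = d_touch * (1.0 - overlap_fraction)
    return contour + anchor + d * u


def make_aggregate_scene(
    seed: int = 0,
    family_specs=None,
    n_isolated: int = 8,
    n_touching_pairs: int = 2,
    n_connected_pairs: int = 2,
    n_triples: int = 2,
    image_shape=(1024, 1024),
    pixel_size: float = 1.0,
    modality: str = "bright_field",
    noise_sd: float = 0.01,
    connected_overlap: float = 0.06,
    **render_kw,
) -> SyntheticScene:
    """Scene mixing isolated particles with touching, connected (necked)
    and three-particle aggregated groups, with per-particle ground truth.

    ``family_specs`` is a list of (label, family, size_px, aspect_ratio)
    tuples cycled over when drawing particles; the default mixes hexagonal
    platelets with rods.
    """
    gen = np.random.default_rng(seed)
    if family_specs is None:
        family_specs = [
            ("hexagon", "hexagon", 60.0, 1.03),
            ("rod", "rod", 46.0, 1.76),
        ]

    def draw_particle(i):
        label, family, size_px, ar = family_specs[i % len(family_specs)]
        theta = float(gen.uniform(-np.pi, np.pi))
        c = make_contour(family, size_px, aspect_ratio=ar, orientation=theta)
        return label, family, size_px, ar, theta, c

    h, w = image_shape
    groups = (
        [("isolated", 1)] * n_isolated
        + [("touching", 2)] * n_touching_pairs
        + [("connected", 2)] * n_connected_pairs
        + [("aggregate", 3)] * n_triples
    )
    contours, labels, rows = [], [], []
    placed_centers = []  # (x, y, bounding radius) per group
    k = 0
    for gi, (kind, n_members) in enumerate(groups):
        members = []
        for j in range(n_members):
            label, family, size_px, ar, theta, c = draw_particle(k)
            k += 1
            if j == 0:
                members.append((label, family, size_px, ar, theta, c))
            else:
                ov = 0.0 if kind == "touching" else connected_overlap
                polys = [ShapelyPolygon(m[5]) for m in members]
                c2 = _place_against(
                    polys, c, (0.0, 0.0), gen.uniform(-np.pi, np.pi), ov, gen
                )
                members.append((label, family, size_px, ar, theta, c2))
        group_pts = np.vstack([m[5] for m in members])
        gc = group_pts.mean(axis=0)
        gr = np.max(np.hypot(*(group_pts - gc).T))
        ok = False
        for _ in range(4000):
            cx = gen.uniform(gr + 4, w - 5 - gr)
            cy = gen.uniform(gr + 4, h - 5 - gr)
            if all(np.hypot(cx - px, cy - py) > gr + pr + 6 for px, py, pr in placed_centers):
                ok = True
                break
        if not ok:
            raise RuntimeError("could not place all groups; enlarge image_shape")
        placed_centers.append((cx, cy, gr))
        shiftv = np.array([cx, cy]) - gc
        for label, family, size_px, ar, theta, c in members:
            cc = c + shiftv
            contours.append(cc)
            labels.append(label)
            cent = centroid(cc)
            rows.append(
                {
                    "label": label,
                    "family": family,
                    "size_nm": size_px * pixel_size,
                    "aspect_ratio": ar,
                    "orientation": theta,
                    "group": kind,
                    "group_id": gi,
                    "cx": cent[0],
                    "cy": cent[1],
                }
            )
    truth = pd.DataFrame(rows)
    truth.insert(0, "particle_id", range(len(truth)))
    return render_scene(
        contours,
        image_shape=image_shape,
        modality=modality,
        noise_sd=noise_sd,
        pixel_size=pixel_size,
        rng=gen,
        labels=labels,
        truth_params=truth,
        seed=seed,
        allow_overlap=True,
        **render_kw,
    )


# ---------------------------------------------------------------------------
# canned scenario recipes


def dispersed_hexrod_spec(n_hex: int = 38, n_rod: int = 5):
    """Well-dispersed distinct shapes: hexagonal platelets (~64.5 nm,
    AR ~1.03) plus a minority of rods (~49 nm, AR ~1.76)."""
    return [
        ClassSpec("hexagon", "hexagon", n_hex, 64.5, 3.0, 1.03, 0.02),
        ClassSpec("rod", "rod", n_rod, 49.0, 1.1, 1.76, 0.05),
    ]


def packed_qd_spec(n1: int = 100, n2: int = 80, size_nm: float = 11.8):
    """Non-distinct rounded shapes forming an aspect-ratio continuum
    (quantum-dot-like): two overlapping classes at AR ~1.12 and ~1.25."""
    return [
        ClassSpec("qd_round", "rounded_cube", n1, size_nm, 0.8, 1.12, 0.05,
                  corner_rounding=0.7, rounding_sd=0.08),
        ClassSpec("qd_elong", "rounded_cube", n2, size_nm, 0.9, 1.25, 0.08,
                  corner_rounding=0.7, rounding_sd=0.08),
    ]


def nanocube_spec(n1: int = 72, n2: int = 18, size_nm: float = 10.8):
    """Cube-like majority plus an elongated quasi-cube minority, intended
    for dark-field rendering with core--shell contrast."""
    return [
        ClassSpec("cube", "rounded_cube", n1, size_nm, 1.1, 1.11, 0.05),
        ClassSpec("quasi_cube", "rounded_cube", n2, size_nm, 1.9, 1.27, 0.09),
    ]
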