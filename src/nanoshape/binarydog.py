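"""Separation of touching and aggregated particles by curvature sign.

At nanometre resolution TEM contrast is dominated by projected thickness,
so the intensity near particle edges has a definite curvature
(Laplacian) sign.  Applying a difference-of-Gaussians operator and
binarizing its sign produces a mask — the "binary DoG" — in which the
interior of every particle is foreground while the crease between
overlapping particles flips sign and separates them.  Known particle
shapes (averaged from previously classified isolated particles) are then
fitted to this mask under bounded affine transforms (anisotropic scale,
skew, rotation, translation); the translation search is exact and fast,
computed for all offsets at once by FFT cross-correlation of the
rasterized contour ring with the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max

from .contours import centroid, ensure_ccw, radius_profile, resample, signed_area, transform
from .descriptors import principal_orientation
from .image import GrayImage

__all__ = [
    "BinaryDoGImage",
    "ShapeTemplate",
    "AffineFit",
    "AffineSearch",
    "compute_binary_dog",
    "average_contour",
    "align_rotation",
    "fft_overlap_scan",
    "fit_templates",
    "rasterize_mask",
]


@dataclass
class BinaryDoGImage:
    """Sign mask of the DoG response (True = particle-interior sign)."""

    mask: np.ndarray
    sigma: float
    ratio: float


@dataclass
class ShapeTemplate:
    """Average unit-area contour of one shape class, canonically oriented."""

    contour: np.ndarray
    class_label: str
    source_count: int
    symmetry_order: int = 1

    def __post_init__(self):
        area = signed_area(self.contour)
        if abs(area - 1.0) > 1e-3:
            raise ValueError(f"template must enclose unit area, got {area:.4f}")


@dataclass
class AffineFit:
    """One template placed in the image by a bounded affine transform.

    ``score`` is the fraction of the contour's interior ring inside the
    binary-DoG mask; ``outer_score`` is the fraction of the ring just
    outside the contour that falls outside the mask.  A correct edge
    placement makes both high; a contour shrunk into a particle interior
    keeps ``score`` = 1 but drives ``outer_score`` to 0.
    """

    template_label: str
    translation: tuple[float, float]
    rotation: float
    scales: tuple[float, float]
    skew: float
    score: float
    fitted_contour: np.ndarray
    outer_score: float = 1.0


@dataclass
class AffineSearch:
    """Grid over the bounded affine parameters (translation is exact/FFT)."""

    rot_step_deg: float = 2.0
    scale_values: tuple = (0.8, 0.85, 0.9, 0.95, 1.0, 1.05, 1.1, 1.15, 1.2)
    skew_values: tuple = (-0.15, -0.1, -0.05, 0.0, 0.05, 0.1, 0.15)

    def rotations(self, symmetry_order: int) -> np.ndarray:
        period = 2 * np.pi / max(symmetry_order, 1)
        n = max(int(round(np.degrees(period) / self.rot_step_deg)), 1)
        return np.arange(n) * period / n


def compute_binary_dog(image: GrayImage, sigma: float, ratio: float = 1.6) -> BinaryDoGImage:
    """Binary sign mask of the difference-of-Gaussians response.

    DoG = G(sigma) - G(ratio*sigma), an approximation to the (negated,
    scaled) Laplacian.  For bright-field images particles are intensity
    minima, so the particle-interior sign is DoG < 0; dark-field inverts.
    The strict inequality leaves an exactly-zero response (e.g. a
    constant image) entirely background.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if ratio <= 1:
        raise ValueError("ratio must exceed 1")
    px = image.pixels
    dog = ndimage.gaussian_filter(px, sigma) - ndimage.gaussian_filter(px, ratio * sigma)
    # dead zone at the float-noise scale: an exactly-flat region (DoG = 0
    # up to rounding) must stay background under the strict sign rule
    tol = 1e-10 * max(1.0, float(np.abs(px).max()))
    mask = dog < -tol if image.modality == "bright_field" else dog > tol
    return BinaryDoGImage(mask=mask, sigma=sigma, ratio=ratio)


def align_rotation(profile: np.ndarray, reference: np.ndarray) -> float:
    """Rotation angle (radians) maximizing circular cross-correlation of a
    radius profile with a reference profile, sub-sample refined."""
    n = len(profile)
    corr = np.fft.irfft(np.fft.rfft(reference) * np.conj(np.fft.rfft(profile)), n)
    j = int(np.argmax(corr))
    # parabolic sub-bin refinement
    y0, y1, y2 = corr[(j - 1) % n], corr[j], corr[(j + 1) % n]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return (j + frac) * 2 * np.pi / n


def _unit_area_centered(contour: np.ndarray) -> np.ndarray:
    c = ensure_ccw(contour)
    c = c - centroid(c)
    return c / np.sqrt(signed_area(c))


def _estimate_symmetry(profile: np.ndarray, max_order: int = 8) -> int:
    """Dominant rotational symmetry order of a radius profile (>= 1)."""
    spec = np.abs(np.fft.rfft(profile - profile.mean()))
    if len(spec) <= 2:
        return 1
    orders = np.arange(2, min(max_order, len(spec) - 1) + 1)
    mags = spec[orders]
    if mags.max() < 1e-6 * max(profile.mean(), 1e-12):
        return 1
    return int(orders[np.argmax(mags)])


def average_contour(contours, M: int = 360, fourier_cutoff: int = 25,
                    class_label: str = "template") -> ShapeTemplate:
    """Average a set of same-class contours into a unit-area template.

    Each contour is scaled to unit area, rotated to its canonical
    principal orientation, and residual (symmetry) rotation is resolved by
    maximal angular cross-correlation of its centroid radius profile with
    the running mean.  The mean profile is Fourier-smoothed (harmonics
    above ``fourier_cutoff`` dropped) and resampled to ``M`` equal
    arc-length points.
    """
    contours = list(contours)
    if not contours:
        raise ValueError("need at least one contour to average")
    profiles = []
    n_theta = max(4 * M, 720)
    for c in contours:
        u = _unit_area_centered(c)
        theta, iso = principal_orientation(u)
        if not iso:
            u = transform(u, rotation=-theta)
        prof = radius_profile(u, n_theta)
        if profiles:
            mean_prof = np.mean(profiles, axis=0)
            shift = align_rotation(prof, mean_prof)
            u = transform(u, rotation=shift)
            prof = radius_profile(u, n_theta)
        profiles.append(prof)
    mean_prof = np.mean(profiles, axis=0)

    spec = np.fft.rfft(mean_prof)
    spec[fourier_cutoff + 1:] = 0.0
    smooth = np.fft.irfft(spec, n_theta)
    ang = np.linspace(-np.pi, np.pi, n_theta, endpoint=False)
    pts = np.column_stack([smooth * np.cos(ang), smooth * np.sin(ang)])
    pts = resample(ensure_ccw(pts), M)
    pts = pts - centroid(pts)
    pts = pts / np.sqrt(signed_area(pts))
    sym = _estimate_symmetry(radius_profile(pts, n_theta))
    return ShapeTemplate(
        contour=pts,
        class_label=class_label,
        source_count=len(contours),
        symmetry_order=sym,
    )


def fft_overlap_scan(ring_mask: np.ndarray, bdog_mask: np.ndarray) -> np.ndarray:
    """Overlap fraction of the ring with the mask for every translation.

    Entry ``(i, j)`` is ``|ring ∩ mask| / |ring|`` with the ring's
    top-left corner at offset ``(i - Hr + 1, j - Wr + 1)`` (full
    correlation range).  Computed via the convolution theorem; overlap
    counts are integers, so the FFT result is rounded and matches the
    brute-force sliding count exactly.
    """
    ring = np.asarray(ring_mask, dtype=float)
    mask = np.asarray(bdog_mask, dtype=float)
    n_ring = ring.sum()
    if n_ring == 0:
        raise ValueError("empty ring mask")
    corr = fftconvolve(mask, ring[::-1, ::-1], mode="full")
    return np.rint(corr) / n_ring


def rasterize_mask(contour: np.ndarray, shape) -> np.ndarray:
    """Filled boolean mask of a contour on a grid of the given shape."""
    m = np.zeros(shape, bool)
    rr, cc = draw_polygon(contour[:, 1], contour[:, 0], shape=shape)
    m[rr, cc] = True
    return m


def _ring_on_canvas(contour: np.ndarray, canvas: int, width: int):
    """Interior and exterior contour rings of the centered contour on a
    fixed square canvas (so every grid configuration shares one FFT size)."""
    pts = contour + canvas / 2.0
    filled = rasterize_mask(pts, (canvas, canvas))
    inner = filled & ~ndimage.binary_erosion(filled, iterations=width)
    outer = ndimage.binary_dilation(filled, iterations=width) & ~filled
    return inner, outer


class _CachedScanner:
    """FFT overlap scans of many same-size rings against one fixed mask,
    reusing the mask transform (the dominant cost of the grid search)."""

    def __init__(self, mask: np.ndarray, canvas: int):
        from scipy.fft import next_fast_len, rfft2

        self.h, self.w = mask.shape
        self.canvas = canvas
        self.fshape = (
            next_fast_len(self.h + canvas - 1),
            next_fast_len(self.w + canvas - 1),
        )
        self.fmask = rfft2(mask.astype(float), self.fshape)

    def scan(self, ring: np.ndarray) -> np.ndarray:
        from scipy.fft import irfft2, rfft2

        fr = rfft2(ring[::-1, ::-1].astype(float), self.fshape)
        corr = irfft2(self.fmask * fr, self.fshape)
        c = self.canvas
        full = corr[: self.h + c - 1, : self.w + c - 1]
        return np.rint(full) / ring.sum()


def _accept_greedy(candidates, iou_max: float, max_fits: int):
    from shapely.geometry import Polygon as _SPoly

    accepted, polys = [], []
    for cand in sorted(candidates, key=lambda c: -(c.score + c.outer_score)):
        p = _SPoly(cand.fitted_contour)
        if not p.is_valid or p.area == 0:
            continue
        ok = True
        for ap in polys:
            inter = p.intersection(ap).area
            union = p.area + ap.area - inter
            if union and inter / union > iou_max:
                ok = False
                break
        if ok:
            accepted.append(cand)
            polys.append(p)
            if len(accepted) >= max_fits:
                break
    return accepted


def fit_templates(
    bdog: BinaryDoGImage,
    templates,
    base_areas,
    search: AffineSearch | None = None,
    score_min: float = 0.85,
    outer_min: float = 0.6,
    max_fits: int = 50,
    ring_width: int = 2,
    iou_max: float = 0.2,
    region_mask: np.ndarray | None = None,
) -> list[AffineFit]:
    """Fit shape templates to the binary DoG mask under affine transforms.

    ``base_areas`` maps each template label to the nominal particle area
    in px^2 (e.g. the median area of isolated particles of that class);
    the grid scale factors multiply the corresponding linear size.  For
    each sampled (rotation, s_x, s_y, skew) the translation scan is exact
    for all integer offsets at once via FFT cross-correlation of the
    rasterized contour ring with the mask.  Candidate placements scoring
    at least ``score_min`` are accepted greedily by descending score,
    suppressing fits that overlap an accepted one by more than ``iou_max``
    area IoU.  ``region_mask`` optionally restricts fit centers to a
    region (e.g. around triaged aggregate contours); the computation is
    then cropped to that region for speed.
    """
    if search is None:
        search = AffineSearch()
    if not templates:
        raise ValueError("need at least one template")
    if not 0 < score_min <= 1:
        raise ValueError("score_min must be in (0, 1]")
    if max(search.scale_values) <= 0:
        raise ValueError("degenerate affine bounds: non-positive scale")
    if not bdog.mask.any():
        return []

    def tmpl_area(tmpl):
        if isinstance(base_areas, dict):
            return float(base_areas[tmpl.class_label])
        return float(base_areas)

    # fixed canvas per template: large enough for the worst grid config
    smax = max(search.scale_values) * (1 + max(abs(s) for s in search.skew_values))
    canvases = {}
    for tmpl in templates:
        ext = np.sqrt(tmpl_area(tmpl)) * smax * np.max(np.abs(tmpl.contour))
        canvases[id(tmpl)] = 2 * int(np.ceil(ext)) + 7

    mask = bdog.mask
    off_xy = np.zeros(2)
    crop_region = region_mask
    if region_mask is not None:
        if not region_mask.any():
            return []
        rows = np.flatnonzero(region_mask.any(axis=1))
        cols = np.flatnonzero(region_mask.any(axis=0))
        pad = max(canvases.values())
        r0 = max(rows[0] - pad, 0)
        r1 = min(rows[-1] + pad + 1, mask.shape[0])
        c0 = max(cols[0] - pad, 0)
        c1 = min(cols[-1] + pad + 1, mask.shape[1])
        mask = mask[r0:r1, c0:c1]
        crop_region = region_mask[r0:r1, c0:c1]
        off_xy = np.array([c0, r0], dtype=float)

    h, w = mask.shape
    scanners = {}
    candidates = []
    for tmpl in templates:
        base_scale = np.sqrt(tmpl_area(tmpl))
        canvas = canvases[id(tmpl)]
        if canvas >= h or canvas >= w:
            continue  # template larger than the (cropped) image
        if canvas not in scanners:
            scanners[canvas] = (
                _CachedScanner(mask, canvas),
                _CachedScanner(~mask, canvas),
            )
        scan_in, scan_out = scanners[canvas]
        for rot, sx, sy, skew in product(
            search.rotations(tmpl.symmetry_order),
            search.scale_values,
            search.scale_values,
            search.skew_values,
        ):
            pts = transform(
                tmpl.contour * base_scale, scale=(sx, sy), rotation=rot, skew=skew
            )
            if abs(signed_area(pts)) < 9:
                raise ValueError("degenerate affine bounds: template collapsed")
            inner, outer = _ring_on_canvas(pts, canvas, ring_width)
            s_in = scan_in.scan(inner)[canvas - 1 : h, canvas - 1 : w]
            if s_in.size == 0 or s_in.max() < score_min:
                continue
            s_out = scan_out.scan(outer)[canvas - 1 : h, canvas - 1 : w]
            combined = np.where(
                (s_in >= score_min) & (s_out >= outer_min), s_in + s_out, 0.0
            )
            if combined.max() <= 0:
                continue
            peaks = peak_local_max(
                combined,
                min_distance=max(3, int(0.2 * base_scale)),
                threshold_abs=score_min + outer_min,
                exclude_border=False,
            )
            for pi, pj in peaks:
                # combined[pi, pj] <=> canvas top-left at crop (row=pi, col=pj)
                fitted = pts + canvas / 2.0 + np.array([pj, pi])
                cen = centroid(fitted)
                if crop_region is not None:
                    ci, cj = int(round(cen[1])), int(round(cen[0]))
                    if not (0 <= ci < h and 0 <= cj < w) or not crop_region[ci, cj]:
                        continue
                fitted = fitted + off_xy
                cen = cen + off_xy
                candidates.append(
                    AffineFit(
                        template_label=tmpl.class_label,
                        translation=(float(cen[0]), float(cen[1])),
                        rotation=float(rot),
                        scales=(float(sx), float(sy)),
                        skew=float(skew),
                        score=float(s_in[pi, pj]),
                        outer_score=float(s_out[pi, pj]),
                        fitted_contour=fitted,
                    )
                )
    return _accept_greedy(candidates, iou_max, max_fits)
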