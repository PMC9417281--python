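"""Micrograph-to-contours conversion.

The pipeline front end: denoise the micrograph, threshold it into a binary
particle mask (resolving bright-field/dark-field polarity and filling
internal core--shell structure), trace one closed contour per connected
component, and triage contours into isolated particles, aggregated
regions, and debris.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import gaussian as _gaussian_filter
from skimage.filters import threshold_local, threshold_otsu

from .contours import as_contour, ensure_ccw, signed_area
from .image import BinaryImage, GrayImage

__all__ = ["denoise", "binarize", "extract_contours", "triage", "solidity"]


def denoise(image: GrayImage, method: str = "fourier_lowpass", cutoff: float = 0.1) -> GrayImage:
    """Smooth the micrograph before thresholding.

    ``fourier_lowpass`` applies a radial low-pass in the Fourier domain
    with a raised-cosine roll-off (hard zero above 1.25x the cutoff); the
    DC term is untouched, so total intensity is preserved exactly.
    ``cutoff`` is in cycles/pixel for the Fourier filter (must be below
    the Nyquist frequency 0.5) and is the Gaussian sigma in pixels for
    ``method="gaussian"``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    px = image.pixels
    if method == "gaussian":
        out = _gaussian_filter(px, sigma=cutoff, preserve_range=True)
    elif method == "fourier_lowpass":
        if cutoff > 0.5:
            raise ValueError("cutoff beyond the Nyquist frequency (0.5 cycles/px)")
        fy = np.fft.fftfreq(px.shape[0])[:, None]
        fx = np.fft.fftfreq(px.shape[1])[None, :]
        f = np.hypot(fy, fx)
        hi = min(1.25 * cutoff, 0.5 + 1e-9)
        h = np.where(
            f <= cutoff,
            1.0,
            np.where(f >= hi, 0.0, 0.5 * (1 + np.cos(np.pi * (f - cutoff) / (hi - cutoff)))),
        )
        out = np.fft.ifft2(np.fft.fft2(px) * h).real
    else:
        raise ValueError(f"unknown denoise method {method!r}")
    return GrayImage(out, pixel_size=image.pixel_size, modality=image.modality)


def binarize(image: GrayImage, threshold_method: str = "otsu", value: float | None = None,
             block_size: int = 101, fill_holes: bool = True) -> BinaryImage:
    """Threshold the micrograph into a particle-foreground mask.

    Polarity is resolved from ``image.modality``: bright-field particles
    are below threshold, dark-field above.  Interior holes (e.g. from
    core--shell contrast rings) are filled so each particle forms one
    solid component.
    """
    px = image.pixels
    # work on a polarity-normalized signal where particles are HIGH
    signal = -px if image.modality == "bright_field" else px
    if threshold_method == "otsu":
        t = threshold_otsu(signal)
        mask = signal > t
    elif threshold_method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding needs a value")
        if not px.min() <= value <= px.max():
            raise ValueError("fixed threshold outside the image intensity range")
        mask = signal > (-value if image.modality == "bright_field" else value)
    elif threshold_method == "adaptive":
        t = threshold_local(signal, block_size=block_size, method="gaussian")
        mask = signal > t
    else:
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    warning = None
    if mask.all():
        warning = "all-foreground mask: thresholding found no background"
    elif not mask.any():
        warning = "all-background mask: thresholding found no particles"
    return BinaryImage(mask, warning=warning)


def _component_contour(mask: np.ndarray, offset_rc) -> np.ndarray:
    """Outer sub-pixel contour of one padded component mask, as (x, y) CCW."""
    cs = measure.find_contours(mask.astype(float), 0.5)
    rc = max(cs, key=len)  # outer boundary is the longest
    xy = np.column_stack([rc[:, 1] + offset_rc[1], rc[:, 0] + offset_rc[0]])
    return ensure_ccw(xy)


def extract_contours(binary: BinaryImage, min_area: float = 20.0) -> list[np.ndarray]:
    """One closed CCW contour per connected foreground component.

    Components touching the image border are excluded (their shape is not
    measurable), as are components smaller than ``min_area`` pixels.
    Tracing is sub-pixel boundary following on the binary mask, which on a
    binarized image is equivalent to edge detection plus edge linking.
    """
    lab, n = ndimage.label(binary.mask)
    if n == 0:
        return []
    h, w = binary.mask.shape
    border_labels = set(np.unique(lab[0, :])) | set(np.unique(lab[-1, :])) | \
        set(np.unique(lab[:, 0])) | set(np.unique(lab[:, -1]))
    contours = []
    for sl, idx in zip(ndimage.find_objects(lab), range(1, n + 1)):
        if idx in border_labels:
            continue
        comp = lab[sl] == idx
        if comp.sum() < min_area:
            continue
        padded = np.pad(comp, 1)
        off = (sl[0].start - 1, sl[1].start - 1)
        contours.append(_component_contour(padded, off))
    return contours


def solidity(contour) -> float:
    """Contour area divided by its convex-hull area (1 for convex shapes)."""
    from scipy.spatial import ConvexHull

    pts = as_contour(contour)
    area = abs(signed_area(pts))
    hull = ConvexHull(pts)
    return area / hull.volume  # "volume" is area in 2-D


def triage(contours, solidity_min: float = 0.95, size_bounds=(20.0, np.inf)):
    """Partition contours into (isolated, aggregated, rejected).

    Isolated: solid (solidity >= threshold) and within the area bounds —
    these go to the shape classifier.  Aggregated: oversized or
    low-solidity regions — candidates for the curvature-sign separation
    stage.  Rejected: sub-minimum debris.
    """
    if not 0 < solidity_min <= 1:
        raise ValueError("solidity_min must be in (0, 1]")
    lo, hi = size_bounds
    isolated, aggregated, rejected = [], [], []
    for c in contours:
        area = abs(signed_area(as_contour(c)))
        if area < lo:
            rejected.append(c)
        elif area > hi or solidity(c) < solidity_min:
            aggregated.append(c)
        else:
            isolated.append(c)
    return isolated, aggregated, rejected
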