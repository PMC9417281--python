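"""Calibrated grayscale micrograph and binary mask containers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GrayImage", "BinaryImage", "MODALITIES"]

MODALITIES = ("bright_field", "dark_field")


@dataclass
class GrayImage:
    """A 2-D micrograph with pixel calibration and contrast polarity.

    ``modality`` records whether particles are darker (``bright_field``,
    e.g. BF-TEM) or brighter (``dark_field``, e.g. ADF-STEM) than the
    background; downstream thresholding and curvature-sign steps use it to
    resolve polarity.
    """

    pixels: np.ndarray
    pixel_size: float = 1.0  # nm per pixel
    modality: str = "bright_field"

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("image must be 2-D")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")

    @property
    def shape(self):
        return self.pixels.shape


@dataclass
class BinaryImage:
    """Foreground (particle) mask aligned with its source image."""

    mask: np.ndarray
    warning: str | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
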