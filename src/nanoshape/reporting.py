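"""Diagnostic outputs for a classified particle ensemble.

Three views summarise a soft classification: responsibility-weighted
density maps of scale- and orientation-matched contours (tight rings for
well-defined shape classes, diffuse clouds for continua), the
eigenvalue scatter (eta1, eta2) with aspect-ratio isolines and the
general-ellipse curve eta2 = 1/(pi*eta1), and class-weighted effective-
diameter histograms.  Each has a data function (CSV-friendly arrays) and
a matplotlib figure wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binarydog import align_rotation
from .contours import centroid, ensure_ccw, radius_profile, resample, signed_area, transform
from .descriptors import ShapeDescriptor

__all__ = [
    "DensityMap",
    "density_map",
    "eigenvalue_scatter_data",
    "diameter_histogram_data",
    "ellipse_curve",
    "plot_density_map",
    "plot_eigenvalue_scatter",
    "plot_diameter_histogram",
]


@dataclass
class DensityMap:
    """Accumulated contour-ring density in normalized shape coordinates."""

    grid: np.ndarray
    class_label: str
    total_weight: float
    extent: float  # grid spans [-extent, extent] in unit-area coordinates


def _normalized_contour(contour, orientation: float, isotropic: bool) -> np.ndarray:
    c = ensure_ccw(contour)
    c = c - centroid(c)
    c = c / np.sqrt(signed_area(c))
    if not isotropic:
        c = transform(c, rotation=-orientation)
    return c


def density_map(
    contours,
    descriptors,
    responsibilities,
    grid_size: int = 256,
    extent: float = 1.2,
    class_label: str = "",
    ring_width: int = 1,
) -> DensityMap:
    """Overlay scale- and orientation-matched contour rings, each weighted
    by its responsibility for the class.

    Residual n-fold symmetry (a hexagon's principal axis is undefined) is
    resolved by maximizing angular cross-correlation of each contour's
    radius profile with the responsibility-weighted running mean profile.
    """
    if not (len(contours) == len(descriptors) == len(responsibilities)):
        raise ValueError("contours, descriptors, responsibilities length mismatch")
    grid = np.zeros((grid_size, grid_size))
    total = 0.0
    n_theta = 720
    mean_prof = None
    mean_w = 0.0
    for c, d, w in zip(contours, descriptors, responsibilities):
        if isinstance(d, ShapeDescriptor):
            theta, iso = d.orientation, d.isotropic
        else:
            theta, iso = float(d["orientation"]), bool(d["isotropic"])
        u = _normalized_contour(c, theta, iso)
        prof = radius_profile(u, n_theta)
        if mean_prof is not None and w > 0:
            shift = align_rotation(prof, mean_prof)
            u = transform(u, rotation=shift)
            prof = radius_profile(u, n_theta)
        if w > 0:
            mean_prof = (
                prof.copy()
                if mean_prof is None
                else (mean_w * mean_prof + w * prof) / (mean_w + w)
            )
            mean_w += w
        if w <= 0:
            continue
        # rasterize the contour stroke onto the grid
        ud = resample(u, 8 * grid_size)
        ij = np.rint((ud + extent) / (2 * extent) * (grid_size - 1)).astype(int)
        ij = ij[(ij[:, 0] >= 0) & (ij[:, 0] < grid_size)
                & (ij[:, 1] >= 0) & (ij[:, 1] < grid_size)]
        stroke = np.zeros_like(grid, dtype=bool)
        stroke[ij[:, 1], ij[:, 0]] = True
        if ring_width > 1:
            from scipy import ndimage

            stroke = ndimage.binary_dilation(stroke, iterations=ring_width - 1)
        grid[stroke] += w
        total += w
    return DensityMap(grid=grid, class_label=class_label, total_weight=total,
                      extent=extent)


def ellipse_curve(eta1: np.ndarray) -> np.ndarray:
    """eta2 along the locus of perfect ellipses of unit area."""
    return 1.0 / (np.pi * np.asarray(eta1, dtype=float))


def eigenvalue_scatter_data(
    descriptors: pd.DataFrame,
    responsibilities: np.ndarray,
    ar_isolines=(1.0, 1.25, 1.5, 1.75, 2.0, 3.0),
    n_curve: int = 200,
):
    """Per-particle (eta1, eta2) with class weights, plus overlay curves.

    Returns a dict with ``points`` (DataFrame eta1, eta2, w_1..w_K),
    ``ar_isolines`` (list of (ar, eta1_line, eta2_line)) and
    ``ellipse_curve`` (eta1, eta2 arrays for eta2 = 1/(pi*eta1)).
    """
    r = np.asarray(responsibilities, dtype=float)
    pts = descriptors[["eta1", "eta2"]].copy()
    for k in range(r.shape[1]):
        pts[f"w_{k + 1}"] = r[:, k]
    e1max = max(pts["eta1"].max() * 1.1, 1.0)
    e1 = np.linspace(1.0 / np.sqrt(np.pi) * 0.9, e1max, n_curve)
    isolines = []
    for ar in ar_isolines:
        # along AR isoline eta1 = ar * eta2; parameterize by eta1
        isolines.append((ar, e1, e1 / ar))
    return {
        "points": pts,
        "ar_isolines": isolines,
        "ellipse_curve": (e1, ellipse_curve(e1)),
    }


def diameter_histogram_data(
    descriptors: pd.DataFrame, responsibilities: np.ndarray, bins: int = 20
):
    """Class-stacked effective-diameter histogram weights.

    Returns (bin_edges, weights) with ``weights[k, b]`` the summed
    responsibility of class k in diameter bin b; total equals N.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    r = np.asarray(responsibilities, dtype=float)
    d = descriptors["d_eff_nm"].to_numpy(dtype=float)
    edges = np.histogram_bin_edges(d, bins=bins)
    weights = np.vstack(
        [np.histogram(d, bins=edges, weights=r[:, k])[0] for k in range(r.shape[1])]
    )
    return edges, weights


# --------------------------------------------------------------------------
# figure wrappers (thin; styling is not part of the contract)

_CLASS_COLORS = ["magenta", "cyan", "orange", "green", "blue"]


def plot_density_map(dmap: DensityMap, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(
        dmap.grid,
        origin="lower",
        extent=[-dmap.extent, dmap.extent, -dmap.extent, dmap.extent],
        cmap="inferno",
    )
    ax.set_title(f"class {dmap.class_label} (sum r = {dmap.total_weight:.1f})")
    ax.set_xlabel("x (unit-area coords)")
    ax.set_ylabel("y")
    return ax


def plot_eigenvalue_scatter(scatter: dict, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = scatter["points"]
    wcols = [c for c in pts.columns if c.startswith("w_")]
    w = pts[wcols].to_numpy()
    colors = np.zeros((len(pts), 3))
    for k, col in enumerate(wcols):
        rgb = np.array(
            {"magenta": (1, 0, 1), "cyan": (0, 1, 1), "orange": (1, 0.6, 0),
             "green": (0, 0.7, 0), "blue": (0, 0, 1)}[_CLASS_COLORS[k % 5]]
        )
        colors += w[:, [k]] * rgb
    ax.scatter(pts["eta1"], pts["eta2"], c=np.clip(colors, 0, 1), s=12)
    for ar, e1, e2 in scatter["ar_isolines"]:
        ax.plot(e1, e2, "-", color="0.7", lw=0.8)
    e1, e2 = scatter["ellipse_curve"]
    ax.plot(e1, e2, "k--", lw=1.0, label="ellipse")
    ax.set_xlabel(r"$\eta_1$")
    ax.set_ylabel(r"$\eta_2$")
    ax.set_ylim(0, None)
    return ax


def plot_diameter_histogram(edges, weights, ax=None, labels=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    bottom = np.zeros(weights.shape[1])
    centers = 0.5 * (edges[:-1] + edges[1:])
    for k in range(weights.shape[0]):
        lbl = labels[k] if labels else f"class {k + 1}"
        ax.bar(centers, weights[k], width=np.diff(edges), bottom=bottom,
               color=_CLASS_COLORS[k % 5], alpha=0.8, label=lbl)
        bottom += weights[k]
    ax.set_xlabel("effective diameter (nm)")
    ax.set_ylabel("weighted count")
    ax.legend()
    return ax
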