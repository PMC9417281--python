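"""Reading and writing of images, contours, templates and scenes.

All intermediate artifacts are plain formats (TIFF/PNG images, CSV/JSON
tables) so every pipeline stage can be inspected and resumed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .binarydog import ShapeTemplate
from .image import GrayImage
from .synthetic import SyntheticScene

__all__ = [
    "read_image",
    "write_image",
    "contours_to_csv",
    "contours_from_csv",
    "contours_to_json",
    "contours_from_json",
    "templates_to_json",
    "templates_from_json",
    "write_scene",
    "read_scene",
]

_FLOAT_FMT = "%.10g"


def read_image(path, pixel_size: float = 1.0, modality: str = "bright_field") -> GrayImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        from PIL import Image

        px = np.asarray(Image.open(path).convert("F"))
    return GrayImage(np.asarray(px, dtype=float), pixel_size=pixel_size, modality=modality)


def write_image(path, image: GrayImage):
    path = Path(path)
    if path.suffix.lower() not in (".tif", ".tiff"):
        raise ValueError("images are written as TIFF")
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def contours_to_csv(contours, path):
    rows = []
    for pid, c in enumerate(contours):
        for x, y in c:
            rows.append((pid, x, y))
    pd.DataFrame(rows, columns=["particle_id", "x", "y"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def contours_from_csv(path):
    df = pd.read_csv(path)
    return [
        g[["x", "y"]].to_numpy(dtype=float)
        for _, g in df.groupby("particle_id", sort=True)
    ]


def contours_to_json(contours, path, labels=None):
    data = [
        {"particle_id": i, "label": None if labels is None else labels[i],
         "points": np.asarray(c).tolist()}
        for i, c in enumerate(contours)
    ]
    Path(path).write_text(json.dumps(data))


def contours_from_json(path):
    data = json.loads(Path(path).read_text())
    contours = [np.asarray(d["points"], dtype=float) for d in data]
    labels = [d.get("label") for d in data]
    return contours, labels


def templates_to_json(templates, path):
    data = [
        {
            "label": t.class_label,
            "points": t.contour.tolist(),
            "source_count": t.source_count,
            "symmetry_order": t.symmetry_order,
        }
        for t in templates
    ]
    Path(path).write_text(json.dumps(data))


def templates_from_json(path):
    data = json.loads(Path(path).read_text())
    return [
        ShapeTemplate(
            contour=np.asarray(d["points"], dtype=float),
            class_label=d["label"],
            source_count=int(d["source_count"]),
            symmetry_order=int(d.get("symmetry_order", 1)),
        )
        for d in data
    ]


def write_scene(scene: SyntheticScene, image_path, truth_path):
    """Persist a synthetic scene as TIFF (image) + JSON (ground truth)."""
    if scene.image is None:
        raise ValueError("scene has no rendered image")
    write_image(image_path, scene.image)
    truth = {
        "seed": scene.seed,
        "pixel_size": scene.image.pixel_size,
        "modality": scene.image.modality,
        "labels": list(scene.truth_labels),
        "contours": [np.asarray(c).tolist() for c in scene.truth_contours],
        "params": scene.truth_params.to_dict(orient="list"),
    }
    Path(truth_path).write_text(json.dumps(truth))


def read_scene(image_path, truth_path) -> SyntheticScene:
    truth = json.loads(Path(truth_path).read_text())
    img = read_image(image_path, pixel_size=truth["pixel_size"],
                     modality=truth["modality"])
    return SyntheticScene(
        image=img,
        truth_contours=[np.asarray(c, dtype=float) for c in truth["contours"]],
        truth_labels=truth["labels"],
        truth_params=pd.DataFrame(truth["params"]),
        seed=truth["seed"],
    )
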