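"""Staged analysis pipeline: micrograph -> contours -> descriptors ->
soft classification -> summaries, with a second pass for aggregates.

Each stage writes plain CSV/JSON artifacts into the run directory, so a
run is resumable and every intermediate is independently inspectable.
Identical configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import binarydog, classify, io, preprocess, reporting
from .contours import signed_area
from .descriptors import describe_all, descriptor_table
from .image import GrayImage

__all__ = ["RunConfig", "AnalysisResult", "run_analyze", "run_aggregates", "run_batch"]

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated parameters for one analysis run."""

    input_path: str | None = None
    pixel_size: float = 1.0
    modality: str = "bright_field"
    denoise_method: str = "fourier_lowpass"
    denoise_cutoff: float = 0.15
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    min_area_px: float = 50.0
    max_area_px: float = float("inf")
    solidity_min: float = 0.95
    n_hu: int = 2
    K_max: int = 5
    selection_criterion: str = "bic"
    prune_weight: float = 0.01
    dog_sigma: float | None = None  # None: 5% of median isolated diameter
    dog_ratio: float = 1.6
    fit_score_min: float = 0.85
    fit_outer_min: float = 0.6
    fit_rot_step_deg: float = 4.0
    fit_scale_values: tuple = (0.9, 0.95, 1.0, 1.05, 1.1)
    fit_skew_values: tuple = (0.0,)
    template_points: int = 360
    template_fourier_cutoff: int = 25
    seed: int = 0
    output_dir: str = "nanoshape_run"

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.modality not in ("bright_field", "dark_field"):
            raise ValueError("modality must be bright_field or dark_field")
        if self.min_area_px <= 0 or self.solidity_min <= 0 or self.K_max < 1:
            raise ValueError("invalid configuration value")
        if self.dog_sigma is not None and self.dog_sigma <= 0:
            raise ValueError("dog_sigma must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path):
        d = asdict(self)
        d["fit_scale_values"] = list(self.fit_scale_values)
        d["fit_skew_values"] = list(self.fit_skew_values)
        d["max_area_px"] = (
            None if np.isinf(self.max_area_px) else self.max_area_px
        )
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


@dataclass
class AnalysisResult:
    """In-memory bundle of one analyze run."""

    contours: list
    aggregated: list
    descriptors: pd.DataFrame
    model: classify.MixtureModel
    classification: classify.Classification
    summary: pd.DataFrame
    templates: list = field(default_factory=list)


def _write_summary(summary: pd.DataFrame, path):
    summary.to_csv(path, index=False, float_format=_FLOAT_FMT)


def _class_templates(result_contours, classification, config) -> list:
    """Average the hard-assigned members of each class into templates."""
    templates = []
    hard = classification.hard_labels
    order = np.argsort(-classification.class_totals, kind="stable")
    for rank, comp in enumerate(order, start=1):
        members = [c for c, h in zip(result_contours, hard) if h == comp]
        if not members:
            continue
        templates.append(
            binarydog.average_contour(
                members,
                M=config.template_points,
                fourier_cutoff=config.template_fourier_cutoff,
                class_label=f"class_{rank}",
            )
        )
    return templates


def run_analyze(
    config: RunConfig, image: GrayImage | None = None, write: bool = True
) -> AnalysisResult:
    """Run the isolated-particle workflow on one micrograph.

    Preprocess -> descriptors -> class-count selection -> soft assignment
    -> summary and report data.  Aggregated (low-solidity / oversized)
    contours are written to a manifest for the aggregate pass.  An empty
    image yields an empty (zero-particle) result and clean exit.
    """
    if image is None:
        if config.input_path is None:
            raise ValueError("config.input_path required when no image is given")
        image = io.read_image(
            config.input_path, pixel_size=config.pixel_size, modality=config.modality
        )
    outdir = Path(config.output_dir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")

    den = preprocess.denoise(image, method=config.denoise_method,
                             cutoff=config.denoise_cutoff)
    binary = preprocess.binarize(den, threshold_method=config.threshold_method,
                                 value=config.threshold_value)
    contours = preprocess.extract_contours(binary, min_area=config.min_area_px)
    isolated, aggregated, _ = preprocess.triage(
        contours,
        solidity_min=config.solidity_min,
        size_bounds=(config.min_area_px, config.max_area_px),
    )

    if not isolated:
        empty = pd.DataFrame()
        if write:
            io.contours_to_csv([], outdir / "contours.csv")
            _write_summary(empty, outdir / "summary.csv")
            io.contours_to_json(aggregated, outdir / "aggregates_manifest.json")
        return AnalysisResult([], aggregated, empty, None, None, empty)

    descs = describe_all(isolated, pixel_size=image.pixel_size, n_hu=config.n_hu)
    table = descriptor_table(descs)
    feats = table[[f"logH{i}" for i in range(1, config.n_hu + 1)]].to_numpy()
    model = classify.select_classes(
        feats,
        K_max=config.K_max,
        criterion=config.selection_criterion,
        prune_weight=config.prune_weight,
        seed=config.seed,
    )
    cls = classify.soft_assign(model, feats)
    summary = classify.class_summary(cls, table)
    templates = _class_templates(isolated, cls, config)

    if write:
        io.contours_to_csv(isolated, outdir / "contours.csv")
        table.to_csv(outdir / "descriptors.csv", index=False, float_format=_FLOAT_FMT)
        resp = pd.DataFrame(
            cls.responsibilities,
            columns=[f"r_{k + 1}" for k in range(model.K)],
        )
        resp.insert(0, "particle_id", table["particle_id"])
        resp.to_csv(outdir / "responsibilities.csv", index=False,
                    float_format=_FLOAT_FMT)
        _write_summary(summary, outdir / "summary.csv")
        io.contours_to_json(aggregated, outdir / "aggregates_manifest.json")
        io.templates_to_json(templates, outdir / "templates.json")
        _write_report(outdir, isolated, table, cls)
    return AnalysisResult(isolated, aggregated, table, model, cls, summary, templates)


def _write_report(outdir, contours, table, cls):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    r = cls.responsibilities
    k = r.shape[1]
    fig, axes = plt.subplots(1, k + 2, figsize=(4 * (k + 2), 4))
    for comp in range(k):
        dm = reporting.density_map(
            contours, table.to_dict("records"), r[:, comp],
            class_label=str(comp + 1),
        )
        reporting.plot_density_map(dm, ax=axes[comp])
    scatter = reporting.eigenvalue_scatter_data(table, r)
    reporting.plot_eigenvalue_scatter(scatter, ax=axes[k])
    edges, weights = reporting.diameter_histogram_data(table, r)
    reporting.plot_diameter_histogram(edges, weights, ax=axes[k + 1])
    fig.tight_layout()
    fig.savefig(outdir / "report.png", dpi=120)
    plt.close(fig)
    scatter["points"].to_csv(outdir / "eigenvalues.csv", index=False,
                             float_format=_FLOAT_FMT)
    hist = pd.DataFrame(weights.T, columns=[f"class_{i + 1}" for i in range(k)])
    hist.insert(0, "bin_left", edges[:-1])
    hist.insert(1, "bin_right", edges[1:])
    hist.to_csv(outdir / "diameter_histogram.csv", index=False,
                float_format=_FLOAT_FMT)


def run_aggregates(
    config: RunConfig,
    image: GrayImage | None = None,
    analysis: AnalysisResult | None = None,
    templates=None,
    write: bool = True,
):
    """Binary-DoG template fitting on the aggregated regions.

    Templates come from a prior :func:`run_analyze` (average contours of
    the classified isolated particles) or from a user file.  Returns
    (fits, merged_summary): the whole-sample summary recomputed with the
    fitted particles included (each fitted particle counts fully towards
    its template's class).
    """
    if image is None:
        if config.input_path is None:
            raise ValueError("config.input_path required when no image is given")
        image = io.read_image(
            config.input_path, pixel_size=config.pixel_size, modality=config.modality
        )
    if analysis is None:
        analysis = run_analyze(config, image=image, write=False)
    if templates is None:
        templates = analysis.templates
    if not templates:
        raise ValueError(
            "no shape templates available: run the analyze stage first or "
            "supply a template file"
        )

    outdir = Path(config.output_dir)
    fits = []
    if analysis.aggregated:
        sigma = config.dog_sigma
        if sigma is None:
            med_d = float(np.median(np.sqrt(analysis.descriptors["area_px"] / np.pi))) * 2
            sigma = max(0.05 * med_d, 1.0)
        bdog = binarydog.compute_binary_dog(image, sigma=sigma, ratio=config.dog_ratio)
        base_areas = _base_areas(analysis)
        search = binarydog.AffineSearch(
            rot_step_deg=config.fit_rot_step_deg,
            scale_values=tuple(config.fit_scale_values),
            skew_values=tuple(config.fit_skew_values),
        )
        for agg in analysis.aggregated:
            region = binarydog.rasterize_mask(agg, image.shape)
            fits.extend(
                binarydog.fit_templates(
                    bdog,
                    templates,
                    base_areas,
                    search=search,
                    score_min=config.fit_score_min,
                    outer_min=config.fit_outer_min,
                    region_mask=region,
                    max_fits=10,
                )
            )

    merged = _merged_summary(analysis, fits, image.pixel_size)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        rows = [
            {
                "template_label": f.template_label,
                "tx": f.translation[0],
                "ty": f.translation[1],
                "rot": f.rotation,
                "sx": f.scales[0],
                "sy": f.scales[1],
                "skew": f.skew,
                "score": f.score,
                "outer_score": f.outer_score,
            }
            for f in fits
        ]
        pd.DataFrame(rows).to_csv(outdir / "aggregate_fits.csv", index=False,
                                  float_format=_FLOAT_FMT)
        io.contours_to_csv([f.fitted_contour for f in fits],
                           outdir / "aggregate_contours.csv")
        _write_summary(merged, outdir / "summary_with_aggregates.csv")
    return fits, merged


def _base_areas(analysis: AnalysisResult) -> dict:
    """Median isolated-particle area per class (hard assignment), keyed by
    the class_{rank} template labels."""
    areas = analysis.descriptors["area_px"].to_numpy()
    hard = analysis.classification.hard_labels
    order = np.argsort(-analysis.classification.class_totals, kind="stable")
    out = {}
    for rank, comp in enumerate(order, start=1):
        sel = areas[hard == comp]
        if len(sel):
            out[f"class_{rank}"] = float(np.median(sel))
    return out


def _merged_summary(analysis: AnalysisResult, fits, pixel_size: float) -> pd.DataFrame:
    from .descriptors import describe

    if analysis.classification is None:
        n_classes = 0
        resp = np.zeros((0, 0))
        table = pd.DataFrame(columns=["d_eff_nm", "AR"])
    else:
        resp = analysis.classification.responsibilities
        order = np.argsort(-analysis.classification.class_totals, kind="stable")
        resp = resp[:, order]  # rank order: class_1 = largest
        n_classes = resp.shape[1]
        table = analysis.descriptors
    rows_d, rows_r = [], []
    for f in fits:
        d = describe(f.fitted_contour, pixel_size=pixel_size)
        rows_d.append({"d_eff_nm": d.effective_diameter, "AR": d.aspect_ratio})
        r = np.zeros(max(n_classes, 1))
        if f.template_label.startswith("class_"):
            k = int(f.template_label.split("_")[1]) - 1
            if k >= len(r):
                r = np.zeros(k + 1)
            r[k] = 1.0
        else:
            r[0] = 1.0
        rows_r.append(r)
    if rows_d:
        kmax = max(n_classes, max(len(r) for r in rows_r))
        all_r = np.zeros((len(table) + len(rows_d), kmax))
        if n_classes:
            all_r[: len(table), :n_classes] = resp
        for i, r in enumerate(rows_r):
            all_r[len(table) + i, : len(r)] = r
        all_t = pd.concat(
            [table[["d_eff_nm", "AR"]], pd.DataFrame(rows_d)], ignore_index=True
        )
    else:
        all_r = resp
        all_t = table
    if all_r.size == 0:
        return pd.DataFrame()
    merged = classify.class_summary(classify.Classification(all_r), all_t)
    return merged


def run_batch(configs, images=None, write: bool = True):
    """Pool descriptors from several micrographs into one classification.

    All images must share a pixel size (the shape features are scale-free,
    but pooled diameters must be commensurate).  Returns a pooled
    AnalysisResult; per-image provenance is kept in the descriptor table.
    """
    if isinstance(configs, RunConfig):
        configs = [configs]
    if images is None:
        images = [None] * len(configs)
    px_sizes = {c.pixel_size for c in configs}
    if len(px_sizes) > 1:
        raise ValueError(
            f"mixed pixel sizes {sorted(px_sizes)}: resample the images or "
            "analyze them separately"
        )
    parts = []
    contours = []
    for i, (cfg, img) in enumerate(zip(configs, images)):
        res = run_analyze(cfg, image=img, write=False)
        if len(res.descriptors):
            t = res.descriptors.copy()
            t["image_index"] = i
            parts.append(t)
            contours.extend(res.contours)
    if not parts:
        return AnalysisResult([], [], pd.DataFrame(), None, None, pd.DataFrame())
    table = pd.concat(parts, ignore_index=True)
    table["particle_id"] = np.arange(len(table))
    cfg0 = configs[0]
    feats = table[[f"logH{i}" for i in range(1, cfg0.n_hu + 1)]].to_numpy()
    model = classify.select_classes(
        feats,
        K_max=cfg0.K_max,
        criterion=cfg0.selection_criterion,
        prune_weight=cfg0.prune_weight,
        seed=cfg0.seed,
    )
    cls = classify.soft_assign(model, feats)
    summary = classify.class_summary(cls, table)
    templates = _class_templates(contours, cls, cfg0)
    if write:
        outdir = Path(cfg0.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "pooled_descriptors.csv", index=False,
                     float_format=_FLOAT_FMT)
        _write_summary(summary, outdir / "pooled_summary.csv")
    return AnalysisResult(contours, [], table, model, cls, summary, templates)
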