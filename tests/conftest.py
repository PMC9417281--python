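"""Shared fixtures: synthetic scenes reused across test modules.

Session scope keeps the rendered scenes and pipeline runs to one
computation each; all generation is seeded and deterministic.
"""

import numpy as np
import pytest

from nanoshape.binarydog import AffineSearch
from nanoshape.pipeline import RunConfig, run_aggregates, run_analyze
from nanoshape.synthetic import (
    dispersed_hexrod_spec,
    make_aggregate_scene,
    make_ensemble,
)

HEXROD_SEED = 11
AGG_SEED = 23


@pytest.fixture(scope="session")
def hexrod_scene():
    """Well-dispersed 38 hexagons + 5 rods (distinct-shape scenario)."""
    return make_ensemble(dispersed_hexrod_spec(), seed=HEXROD_SEED,
                         image_shape=(1024, 1024))


@pytest.fixture(scope="session")
def hexrod_analysis(hexrod_scene, tmp_path_factory):
    cfg = RunConfig(seed=HEXROD_SEED,
                    output_dir=str(tmp_path_factory.mktemp("hexrod")))
    return run_analyze(cfg, image=hexrod_scene.image)


def coarse_search():
    """Reduced affine grid used in tests (same algorithm, smaller sweep)."""
    return AffineSearch(rot_step_deg=4.0,
                        scale_values=(0.9, 0.95, 1.0, 1.05, 1.1),
                        skew_values=(0.0,))


def aggregate_config(outdir) -> RunConfig:
    return RunConfig(
        seed=AGG_SEED,
        output_dir=str(outdir),
        min_area_px=100.0,
        max_area_px=1.3 * np.pi * 31**2,
        fit_rot_step_deg=4.0,
        fit_scale_values=(0.9, 0.95, 1.0, 1.05, 1.1),
        fit_skew_values=(0.0,),
    )


@pytest.fixture(scope="session")
def aggregate_scene():
    """20 particles: 9 isolated, 2 touching pairs, 2 connected pairs and a
    3-particle aggregate (hexagons + rods)."""
    return make_aggregate_scene(
        seed=AGG_SEED,
        image_shape=(900, 900),
        n_isolated=9,
        n_touching_pairs=2,
        n_connected_pairs=2,
        n_triples=1,
    )


@pytest.fixture(scope="session")
def aggregate_run(aggregate_scene, tmp_path_factory):
    """Full isolated + aggregate pass on the 20-particle scene."""
    cfg = aggregate_config(tmp_path_factory.mktemp("agg"))
    analysis = run_analyze(cfg, image=aggregate_scene.image, write=False)
    fits, merged = run_aggregates(
        cfg, image=aggregate_scene.image, analysis=analysis, write=False
    )
    return {"scene": aggregate_scene, "analysis": analysis,
            "fits": fits, "merged": merged}


def iou(poly_a, poly_b) -> float:
    from shapely.geometry import Polygon

    pa, pb = Polygon(poly_a), Polygon(poly_b)
    inter = pa.intersection(pb).area
    union = pa.area + pb.area - inter
    return inter / union if union else 0.0
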