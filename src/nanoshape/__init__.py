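"""nanoshape: soft shape classification and metrology of convex
nanoparticles from TEM micrographs.

The pipeline converts a calibrated micrograph into per-particle contours,
summarises each contour by log-Hu-moment shape descriptors and the shape
eigenvalues (eta1, eta2), soft-classifies the ensemble with a Gaussian
mixture model in feature space, and reports responsibility-weighted size
and shape statistics.  Touching or aggregated particles are handled by a
curvature-sign (binary difference-of-Gaussians) mask to which averaged
class shape templates are fitted under bounded affine transforms.
"""

from .classify import (
    Classification,
    MixtureModel,
    class_summary,
    fit_gmm,
    select_classes,
    soft_assign,
)
from .descriptors import (
    ShapeDescriptor,
    describe,
    describe_all,
    descriptor_table,
    effective_diameter,
    hu_features,
    polygon_moments,
    principal_orientation,
    shape_eigenvalues,
)
from .image import BinaryImage, GrayImage
from .pipeline import AnalysisResult, RunConfig, run_aggregates, run_analyze, run_batch
from .preprocess import binarize, denoise, extract_contours, triage
from .synthetic import (
    ClassSpec,
    SyntheticScene,
    dispersed_hexrod_spec,
    make_aggregate_scene,
    make_contour,
    make_ensemble,
    nanocube_spec,
    packed_qd_spec,
    render_scene,
)

__version__ = "0.1.0"

__all__ = [name for name in dir() if not name.startswith("_")]
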