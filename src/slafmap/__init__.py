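"""slafmap: F2 genetic linkage maps from SLAF-seq style marker data.

Simulation, marker identification, Bayesian genotype calling, QC and
segregation testing, two-point EM linkage, SARF/simulated-annealing
ordering with SMOOTH error correction and kNN imputation, Kosambi map
distances, and map reporting with segregation-distortion regions.
"""

from importlib.resources import files as _files
import json as _json

from .simdata import SimConfig, DistortionLocus, TruthSet, simulate_meioses, simulate_reads, simulate_dataset
from .genotype_calling import genotype_posterior, call_matrix, iterative_quality_prune, GenotypeMatrix
from .marker_qc import chi_square_121, apply_filters, QcConfig
from .linkage import estimate_r_em, lod_score, pairwise_r_lod, group_markers
from .ordering import (sarf, order_sa, multipoint_update, smooth_correct,
                       knn_impute, kosambi, kosambi_inverse, insert_skewed,
                       build_group_map, LinkageGroup)
from .report import map_stats, summary_ratios, percent, detect_sdr, write_outputs, round_half_up
from .pipeline import PipelineConfig, run_pipeline

__version__ = "0.1.0"


def published_counts() -> dict:
    """The bundled published count tables used for desk-scale arithmetic."""
    return _json.loads(_files("slafmap.data").joinpath("published_counts.json").read_text())
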