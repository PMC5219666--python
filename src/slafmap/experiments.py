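"""Canned simulation experiments for validation and benchmarking.

These define the study conditions used by the package's recovery checks:
an F2 of 130 individuals genotyped at ~3x depth with 1% per-read error
and ~15% missing data, across ten chromosomes with two gamete-viability
selection loci (s = 0.8).  The two distorted chromosomes are made longer
(180 cM) because at this population size an s = 0.8 locus significantly
skews markers up to ~70 cM away — a shorter chromosome would retain no
Mendelian framework at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from .marker_qc import QcConfig
from .pipeline import PipelineConfig, PipelineResult, run_pipeline
from .simdata import DistortionLocus, SimConfig, simulate_dataset, TruthSet

__all__ = ["recovery_config", "recovery_pipeline_config", "run_recovery",
           "RecoveryMetrics", "evaluate_recovery", "sdr_replicate"]

DISTORTION_LOCI = ((2, 3.0, 0.8, "a"), (7, 177.0, 0.8, "b"))


def recovery_config(seed: int) -> SimConfig:
    """The ten-chromosome map-recovery experiment."""
    rng = np.random.default_rng(7)  # fixed genome layout; seed drives the data
    lengths = np.round(rng.uniform(110, 130, 10), 1)
    lengths[1] = 180.0
    lengths[6] = 180.0
    n_markers = rng.integers(22, 29, 10)
    n_markers[1] = 30
    n_markers[6] = 30
    positions = tuple(np.linspace(0.0, L, int(k)) for L, k in zip(lengths, n_markers))
    return SimConfig(
        n_chromosomes=10,
        chrom_lengths_cM=tuple(lengths),
        markers_per_chrom=tuple(int(k) for k in n_markers),
        n_individuals=130,
        parent_depth_mean=40.0,
        offspring_depth_mean=3.0,
        seq_error_rate=0.01,
        missing_extra_rate=0.10,
        polymorphic_fraction=1.0,
        marker_positions=positions,
        distortion_loci=tuple(DistortionLocus(*d) for d in DISTORTION_LOCI),
        seed=seed,
    )


def recovery_pipeline_config(seed: int = 1) -> PipelineConfig:
    """Pipeline settings for the recovery experiment.

    The progeny depth threshold is matched to the simulated 3x regime
    (a >3-fold cutoff would sit exactly on the Poisson mean and remove
    half the markers by chance); grouping uses the robust 2-edge rule on
    the margin-free modified LOD.
    """
    return PipelineConfig(seed=seed, qc=QcConfig(min_progeny_depth=2.0),
                          grouping_mode="robust")


def run_recovery(seed: int):
    """Simulate the recovery experiment and run the pipeline on it."""
    cfg = recovery_config(seed)
    truth, reads = simulate_dataset(cfg)
    result = run_pipeline(reads.count_a, reads.count_b,
                          config=recovery_pipeline_config(seed=1))
    return truth, reads, result


@dataclass
class RecoveryMetrics:
    n_groups: int
    n_mixed_groups: int          # groups spanning more than one true chromosome
    per_group_tau: list          # |Kendall tau| vs true positions, per group
    total_length_ratio: float    # estimated / simulated total map length
    imputation_accuracy: float   # imputed entries matching the true genotype
    n_sdrs: int
    loci_with_sdr: int           # distortion loci overlapped by >= 1 SDR


def evaluate_recovery(truth: TruthSet, result: PipelineResult,
                      reads=None, locus_margin_cM: float = 20.0) -> RecoveryMetrics:
    """Score a pipeline result against the simulator ground truth.

    When ``reads`` is given, imputation accuracy is measured on exactly
    the entries the pipeline filled in (raw call missing, completed call
    present); otherwise it is the concordance of all completed calls.
    """
    pos_of = truth.positions.set_index("marker_id")
    taus = []
    mixed = 0
    for g in result.groups:
        true_pos = [float(pos_of.loc[m, "cM"]) for m in g.marker_ids]
        chroms = {int(pos_of.loc[m, "chrom"]) for m in g.marker_ids}
        if len(chroms) > 1:
            mixed += 1
        tau = kendalltau(true_pos, range(len(true_pos))).statistic
        taus.append(abs(float(tau)) if tau == tau else 0.0)

    # imputation accuracy over the entries the pipeline filled in
    raw = None
    if reads is not None:
        from .genotype_calling import call_matrix
        prog = [c for c in reads.count_a.columns if not c.startswith("P")]
        raw = call_matrix(reads.count_a[prog], reads.count_b[prog]).codes
    correct = total = 0
    truth_g = truth.genotypes
    for g in result.groups:
        codes = result.group_codes.get(g.lg_id)
        if codes is None:
            continue
        fw_ids_in_order = [m for m, acc in zip(g.marker_ids, g.accessory) if not acc]
        for row, mid in enumerate(fw_ids_in_order):
            true_row = truth_g.loc[mid].to_numpy()
            est = codes[row]
            scored = est >= 0
            if raw is not None:
                scored &= raw.loc[mid].to_numpy() == -1
            correct += int(np.sum((est == true_row) & scored))
            total += int(scored.sum())
    accuracy = correct / total if total else float("nan")

    hits = 0
    for d in truth.distortion_loci:
        found = False
        for s in result.sdrs:
            marks = [s.start_marker, s.end_marker]
            chroms = {int(pos_of.loc[m, "chrom"]) for m in marks}
            if chroms != {d.chromosome}:
                continue
            lo = min(float(pos_of.loc[m, "cM"]) for m in marks)
            hi = max(float(pos_of.loc[m, "cM"]) for m in marks)
            if lo - locus_margin_cM <= d.position_cM <= hi + locus_margin_cM:
                found = True
                break
        hits += found

    sim_total = sum(truth.config.chrom_lengths_cM)
    return RecoveryMetrics(
        n_groups=len(result.groups),
        n_mixed_groups=mixed,
        per_group_tau=taus,
        total_length_ratio=result.summary.total_distance_cM / sim_total,
        imputation_accuracy=accuracy,
        n_sdrs=len(result.sdrs),
        loci_with_sdr=hits,
    )


def sdr_replicate(seed: int, s: float = 0.8) -> bool:
    """One small segregation-distortion recovery replicate.

    A clean 120 cM chromosome plus a 180 cM chromosome carrying a
    near-terminal viability locus;
    returns True when the pipeline detects at least one SDR whose span
    (true coordinates of its end markers, plus a 20 cM margin) covers the
    locus.
    """
    cfg = SimConfig(
        n_chromosomes=2, chrom_lengths_cM=(120.0, 180.0),
        markers_per_chrom=(25, 30), n_individuals=130,
        parent_depth_mean=40.0, offspring_depth_mean=3.0,
        seq_error_rate=0.01, missing_extra_rate=0.10,
        polymorphic_fraction=1.0,
        marker_positions=(np.linspace(0, 120, 25), np.linspace(0, 180, 30)),
        distortion_loci=(DistortionLocus(2, 3.0, s, "a"),),
        seed=seed,
    )
    truth, reads = simulate_dataset(cfg)
    result = run_pipeline(reads.count_a, reads.count_b,
                          config=recovery_pipeline_config(seed=1))
    metrics = evaluate_recovery(truth, result)
    return metrics.loci_with_sdr >= 1
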