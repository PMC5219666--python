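"""End-to-end map construction from an allele-count matrix.

Orchestrates the full analysis: parent genotype screening (only markers
where the two parents are opposite homozygotes — the aa x bb pattern — are
informative in this F2 design), Bayesian progeny genotype calling, the QC
cascade with the 1:2:1 chi-square test, MLOD grouping, per-group ordering
with error correction and imputation, Kosambi positioning, accessory
(distorted) marker insertion, and SDR detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genotype_calling as gc
from . import marker_qc as qc
from .linkage import (pairwise_r_lod, pairwise_r_lod_counts, group_markers,
                      group_markers_plateau, group_markers_robust,
                      correlation_lod, MISSING)
from .ordering import (LinkageGroup, build_group_map, insert_skewed,
                       insert_skewed_gl)
from .report import MapSummary, Sdr, detect_sdr, map_stats

__all__ = ["PipelineConfig", "PipelineResult", "screen_parents", "run_pipeline"]


@dataclass
class PipelineConfig:
    error_rate: float = 0.01
    estimation: str = "gl"              # "gl": genotype-likelihood linkage; "calls": hard calls
    parent_error_rate: float = 0.01
    min_parent_posterior: float = 0.95  # confidence required to call a parent
    min_call_posterior: float = 0.6     # linkage-matrix calls below this become missing
    obs_error_rate: float = 0.05        # initial miscall rate for error-aware EM
    estimate_obs_error: bool = True     # re-estimate the miscall rate per group
    gq_cutoff: float | None = None      # mean-quality pruning; None disables
    qc: qc.QcConfig = field(default_factory=qc.QcConfig)
    mlod_threshold: float = 5.0
    grouping_mode: str = "threshold"    # "robust" (2-edge components) or "plateau"
    robust_edge_lod: float = 4.0        # per-edge LOD when grouping_mode="robust"
    min_group_size: int = 2
    n_cycles: int = 3
    smooth_threshold: float = 1e-3
    knn_k: int = 5
    accessory_lod_threshold: float = 5.0
    assoc_veto_lod: float = 4.0         # required margin-free association for accessory edges
    sdr_min_run: int = 3
    seed: int = 0


@dataclass
class PipelineResult:
    groups: list            # finished LinkageGroups (accessory included)
    group_codes: dict       # lg_id -> corrected+imputed codes in map order
    qc_results: list
    partition: dict
    summary: MapSummary
    sdrs: list
    unplaced_accessory: list
    logs: dict

    @property
    def mapped_marker_ids(self) -> list:
        out = []
        for g in self.groups:
            out.extend(g.marker_ids)
        return out


def screen_parents(count_a: pd.DataFrame, count_b: pd.DataFrame,
                   parent_cols=("P1", "P2"), error_rate: float = 0.01,
                   min_posterior: float = 0.95) -> pd.DataFrame:
    """Call both parents per marker and keep the aa x bb pattern.

    Parents are (near-)homozygous lines, so calls use a homozygote-weighted
    prior.  Returns a frame indexed by marker with columns 'p1', 'p2'
    (codes) and 'usable' (both parents confidently homozygous and
    different).
    """
    prior = (0.495, 0.01, 0.495)
    out = {}
    for name, col in zip(("p1", "p2"), parent_cols):
        calls = gc.call_matrix(count_a[[col]], count_b[[col]],
                               error_rate=error_rate, priors=prior,
                               min_posterior=min_posterior)
        out[name] = calls.codes[col]
    frame = pd.DataFrame(out)
    frame["usable"] = (
        frame["p1"].isin([gc.AA, gc.BB])
        & frame["p2"].isin([gc.AA, gc.BB])
        & (frame["p1"] != frame["p2"])
    )
    return frame


def run_pipeline(count_a: pd.DataFrame, count_b: pd.DataFrame,
                 parent_cols=("P1", "P2"),
                 config: PipelineConfig | None = None) -> PipelineResult:
    """Build a genetic map from a (markers x samples) allele-count pair.

    ``count_a``/``count_b`` must include the two parent columns; all other
    columns are progeny.  Raises RuntimeError when no marker survives the
    parent screen or QC.
    """
    cfg = config or PipelineConfig()
    logs: dict = {}

    parents = screen_parents(count_a, count_b, parent_cols,
                             cfg.parent_error_rate, cfg.min_parent_posterior)
    usable = parents.index[parents["usable"]]
    if len(usable) == 0:
        raise RuntimeError("no marker shows the aa x bb parental pattern")
    logs["n_usable_markers"] = int(len(usable))

    progeny_cols = [c for c in count_a.columns if c not in parent_cols]
    ca = count_a.loc[usable, progeny_cols]
    cb = count_b.loc[usable, progeny_cols]
    # orient each marker so allele 'a' is the maternal (P1) allele
    flip = parents.loc[usable, "p1"] == gc.BB
    ca, cb = ca.where(~flip, cb), cb.where(~flip, ca)

    # Full call set: every non-zero-depth call, used for segregation testing
    # and integrity (the 1:2:1 prior keeps aggregate ratios unbiased even at
    # shallow depth).  The linkage call set additionally masks low-posterior
    # calls, trading missingness for a much lower miscall rate.
    matrix = gc.call_matrix(ca, cb, error_rate=cfg.error_rate)
    if cfg.gq_cutoff is not None:
        matrix, prune_log = gc.iterative_quality_prune(matrix, cfg.gq_cutoff)
        logs["pruned"] = prune_log
        ca = ca.loc[matrix.marker_ids, matrix.individuals]
        cb = cb.loc[matrix.marker_ids, matrix.individuals]
    map_matrix = gc.call_matrix(ca, cb, error_rate=cfg.error_rate,
                                min_posterior=cfg.min_call_posterior)

    parent_depth = (
        count_a.loc[matrix.marker_ids, list(parent_cols)].sum(axis=1)
        + count_b.loc[matrix.marker_ids, list(parent_cols)].sum(axis=1)
    ) / 2.0
    qc_results, partition = qc.apply_filters(matrix, parent_depth, cfg.qc)
    logs["partition_sizes"] = {k: len(v) for k, v in partition.items()}

    fw_ids = partition["framework"]
    acc_ids = partition["accessory"]
    if not fw_ids:
        raise RuntimeError("no framework marker survived QC")
    fw_codes = map_matrix.codes.loc[fw_ids].to_numpy(dtype=np.int8)
    acc_codes_all = map_matrix.codes.loc[acc_ids].to_numpy(dtype=np.int8) \
        if acc_ids else np.empty((0, fw_codes.shape[1]), dtype=np.int8)
    joint_ids = list(fw_ids) + list(acc_ids)
    nf = len(fw_ids)

    # Grouping covers framework AND accessory markers so a distorted region
    # cannot orphan its chromosome.  The edge statistic is the modified
    # (margin-robust) LOD: Fisher-Z correlation of genotype dosages, which
    # unlinked-but-distorted marker pairs cannot inflate the way they
    # inflate the model-based linkage LOD.
    mlod = correlation_lod(matrix.codes.loc[joint_ids].to_numpy(dtype=np.int8))
    if cfg.grouping_mode == "plateau":
        grouping = group_markers_plateau(mlod, min_group_size=cfg.min_group_size)
    elif cfg.grouping_mode == "robust":
        grouping = group_markers_robust(mlod, cfg.robust_edge_lod,
                                        strong_single_lod=2 * cfg.robust_edge_lod)
    else:
        grouping = group_markers(mlod, cfg.mlod_threshold)
    logs["n_unlinked"] = len(grouping.unlinked)

    # a component made only of distorted markers (a selection region with no
    # Mendelian backbone of its own) is attached to the framework-bearing
    # group it links best, so it can be inserted rather than dropped
    fw_bearing = [grp for grp in grouping.groups
                  if sum(1 for i in grp if i < nf) >= cfg.min_group_size]
    orphan = [grp for grp in grouping.groups
              if sum(1 for i in grp if i < nf) < cfg.min_group_size]
    final_groups = [list(grp) for grp in fw_bearing]
    dropped: list = []
    for grp in orphan:
        best, best_lod = None, cfg.robust_edge_lod
        for gi, host in enumerate(final_groups):
            link = float(mlod[np.ix_(grp, host)].max()) if host else 0.0
            if link >= best_lod:
                best, best_lod = gi, link
        if best is None:
            dropped.extend(grp)
        else:
            final_groups[best].extend(grp)
    grouping.groups = [sorted(grp) for grp in final_groups]
    logs["n_dropped_components"] = len(dropped)

    if cfg.estimation == "gl":
        gl_all = gc.genotype_likelihoods(ca.to_numpy(), cb.to_numpy(),
                                         cfg.error_rate)
        row_of = {mid: i for i, mid in enumerate(ca.index)}

    groups: list[LinkageGroup] = []
    group_codes: dict = {}
    unplaced: list = []
    lg_id = 0
    for members in grouping.groups:
        fw_members = [i for i in members if i < nf]
        acc_members = [i - nf for i in members if i >= nf]
        if len(fw_members) < cfg.min_group_size:
            unplaced.extend(acc_ids[a] for a in acc_members)
            continue
        lg_id += 1
        ids = [fw_ids[i] for i in fw_members]
        sub = fw_codes[fw_members]
        counts = None
        if cfg.estimation == "gl":
            counts = (ca.loc[ids].to_numpy(), cb.loc[ids].to_numpy())
        group, completed, glog = build_group_map(
            sub, ids, lg_id=lg_id, seed=cfg.seed + lg_id,
            n_cycles=cfg.n_cycles, smooth_threshold=cfg.smooth_threshold,
            knn_k=cfg.knn_k, obs_error=cfg.obs_error_rate,
            estimate_error=cfg.estimate_obs_error,
            counts=counts, error_rate=cfg.error_rate,
        )
        group_codes[lg_id] = completed
        logs.setdefault("group_logs", {})[lg_id] = {
            "n_smooth_changes": len(glog["smooth_changes"]),
            "cycles": glog["cycles"],
        }

        if acc_members:
            # insertion order: strongest-linked first, scored by modified
            # LOD to the group's framework markers (chain anchors grow as
            # markers are placed, so weakly anchored ones go last)
            fw_cols = np.array(fw_members)
            scores = np.array([float(mlod[nf + a, fw_cols].max())
                               for a in acc_members])
            aids = [acc_ids[a] for a in acc_members]
            if cfg.estimation == "gl":
                fw_gl = np.stack([gl_all[row_of[m]] for m in group.marker_ids])
                acc_gl = np.stack([gl_all[row_of[a]] for a in aids])
                group, not_placed = insert_skewed_gl(
                    group, fw_gl, acc_gl, aids, max_lod=scores,
                    lod_threshold=0.0,
                )
                from .ordering import reorder_accessory_runs
                rows = [row_of[m] for m in group.marker_ids]
                group = reorder_accessory_runs(
                    group, gl_all[rows], ca.to_numpy()[rows], cb.to_numpy()[rows],
                    error_rate=cfg.error_rate, seed=cfg.seed + 31 * lg_id,
                )
            else:
                fw_in_order = np.vstack(
                    [fw_codes[fw_ids.index(m)] for m in group.marker_ids])
                group, not_placed = insert_skewed(
                    group, fw_in_order, acc_codes_all[acc_members], aids,
                    lod_threshold=cfg.accessory_lod_threshold,
                    lod_to_framework=mlod[np.ix_([nf + a for a in acc_members],
                                                 fw_cols)],
                )
            unplaced.extend(not_placed)
        groups.append(group)

    distorted = {mid: (mid in set(acc_ids)) for mid in
                 [m for g in groups for m in g.marker_ids]}
    sdrs: list[Sdr] = []
    for g in groups:
        sdrs.extend(detect_sdr(g, distorted, min_run=cfg.sdr_min_run))

    summary = map_stats(groups)
    return PipelineResult(
        groups=groups, group_codes=group_codes, qc_results=qc_results,
        partition=partition, summary=summary, sdrs=sdrs,
        unplaced_accessory=unplaced, logs=logs,
    )
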