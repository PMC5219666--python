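"""Map summary statistics, segregation distortion regions, and output files.

Conventions used throughout the summaries (chosen to match how such maps
are conventionally tabulated): per-group average adjacent distance is
total distance / (marker count - 1); overall averages are unweighted means
of the per-group values; percentages are 100 * part / whole rounded
half-up at the printed precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd

from .ordering import LinkageGroup

__all__ = ["LgStats", "MapSummary", "Sdr", "round_half_up", "map_stats",
           "summary_ratios", "percent", "detect_sdr", "write_outputs"]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (table style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class LgStats:
    lg_id: int
    n_markers: int
    total_distance_cM: float
    avg_distance_cM: float
    largest_gap_cM: float
    pct_gaps_le5: float


@dataclass
class MapSummary:
    per_lg: list
    total_markers: int
    total_distance_cM: float
    mean_markers_per_lg: float
    mean_avg_distance_cM: float
    mean_largest_gap_cM: float
    mean_pct_gaps_le5: float


@dataclass(frozen=True)
class Sdr:
    """A segregation distortion region: a maximal run of distorted markers."""

    lg_id: int
    start_marker: str
    end_marker: str
    n_markers: int
    start_cM: float
    end_cM: float


def _lg_stats(lg_id: int, positions: np.ndarray) -> LgStats:
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n < 2:
        return LgStats(lg_id, n, 0.0, 0.0, 0.0, 0.0)
    gaps = np.diff(positions)
    total = float(positions[-1] - positions[0])
    return LgStats(
        lg_id=lg_id,
        n_markers=n,
        total_distance_cM=total,
        avg_distance_cM=total / (n - 1),
        largest_gap_cM=float(gaps.max()),
        pct_gaps_le5=100.0 * float((gaps <= 5.0).sum()) / (n - 1),
    )


def map_stats(groups: list[LinkageGroup]) -> MapSummary:
    """Summarize a finished genetic map.

    Per group: total distance, average adjacent distance (over n-1
    intervals), largest gap, and the percentage of gaps <= 5.0 cM.
    Overall figures: total markers, summed distance, and unweighted means
    of the per-group values.  Values are unrounded; use
    :func:`round_half_up` when printing.
    """
    per = [_lg_stats(g.lg_id, g.positions) for g in groups]
    multi = [s for s in per if s.n_markers >= 2]
    return MapSummary(
        per_lg=per,
        total_markers=sum(s.n_markers for s in per),
        total_distance_cM=sum(s.total_distance_cM for s in per),
        mean_markers_per_lg=float(np.mean([s.n_markers for s in per])) if per else 0.0,
        mean_avg_distance_cM=float(np.mean([s.avg_distance_cM for s in multi])) if multi else 0.0,
        mean_largest_gap_cM=float(np.mean([s.largest_gap_cM for s in multi])) if multi else 0.0,
        mean_pct_gaps_le5=float(np.mean([s.pct_gaps_le5 for s in multi])) if multi else 0.0,
    )


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """100 * part / whole rounded half-up; raises on a zero denominator."""
    if whole == 0:
        raise ZeroDivisionError("percentage undefined: zero denominator")
    return round_half_up(100.0 * part / whole, ndigits)


def summary_ratios(count_table: dict[str, float], whole_key: str | None = None,
                   ndigits: int = 1) -> dict[str, float]:
    """Percentage table from an integer count table.

    Each value becomes 100 * count / whole, rounded half-up at ``ndigits``
    decimals.  ``whole_key`` names the denominator entry; by default the
    denominator is the sum of all entries.
    """
    whole = count_table[whole_key] if whole_key else sum(count_table.values())
    return {k: percent(v, whole, ndigits) for k, v in count_table.items()}


def detect_sdr(group: LinkageGroup, distorted: dict, min_run: int = 3) -> list[Sdr]:
    """Find segregation distortion regions on one linkage group.

    An SDR is a maximal run of at least ``min_run`` consecutive markers
    flagged as distorted; the result is invariant to reversing the group's
    orientation.  ``distorted`` maps marker_id -> bool.
    """
    flags = [bool(distorted.get(mid, False)) for mid in group.marker_ids]
    sdrs: list[Sdr] = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                sdrs.append(Sdr(
                    lg_id=group.lg_id,
                    start_marker=group.marker_ids[i],
                    end_marker=group.marker_ids[j],
                    n_markers=j - i + 1,
                    start_cM=float(group.positions[i]),
                    end_cM=float(group.positions[j]),
                ))
            i = j + 1
        else:
            i += 1
    return sdrs


MAP_HEADER = ["marker_id", "lg", "position_cM", "accessory"]
SUMMARY_HEADER = ["lg", "n_markers", "total_distance_cM", "avg_distance_cM",
                  "largest_gap_cM", "pct_gaps_le5"]
SNP_TYPE_HEADER = ["snp_type", "count", "pct"]
DISTORTION_HEADER = ["lg", "n_markers", "n_distorted", "pct_distorted", "n_sdr"]


def write_outputs(out_dir, groups: list[LinkageGroup],
                  snp_type_counts: dict[str, int] | None = None,
                  distorted: dict | None = None,
                  sdrs: list[Sdr] | None = None,
                  manifest: dict | None = None) -> dict[str, Path]:
    """Write the map and its summary tables as deterministic TSV files.

    Emits: ``map.tsv`` (marker, group, position, accessory flag),
    ``map_summary.tsv`` (per-group statistics plus a Total row),
    ``snp_types.tsv``, ``distortion.tsv`` (per-group distorted counts and
    SDRs; zero-row but valid when there are no accessory markers), and a
    ``manifest.json`` run record.  Output is byte-stable for fixed inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    rows = []
    for g in groups:
        for mid, pos, acc in zip(g.marker_ids, g.positions, g.accessory):
            rows.append({"marker_id": mid, "lg": g.lg_id,
                         "position_cM": f"{pos:.3f}", "accessory": int(acc)})
    files["map"] = out / "map.tsv"
    pd.DataFrame(rows, columns=MAP_HEADER).to_csv(files["map"], sep="\t", index=False)

    summ = map_stats(groups)
    srows = []
    for s in summ.per_lg:
        srows.append({
            "lg": s.lg_id, "n_markers": s.n_markers,
            "total_distance_cM": f"{round_half_up(s.total_distance_cM, 1):.1f}",
            "avg_distance_cM": f"{round_half_up(s.avg_distance_cM, 2):.2f}",
            "largest_gap_cM": f"{round_half_up(s.largest_gap_cM, 1):.1f}",
            "pct_gaps_le5": f"{round_half_up(s.pct_gaps_le5, 1):.1f}",
        })
    srows.append({
        "lg": "Total", "n_markers": summ.total_markers,
        "total_distance_cM": f"{round_half_up(summ.total_distance_cM, 1):.1f}",
        "avg_distance_cM": f"{round_half_up(summ.mean_avg_distance_cM, 2):.2f}",
        "largest_gap_cM": f"{round_half_up(summ.mean_largest_gap_cM, 1):.1f}",
        "pct_gaps_le5": f"{round_half_up(summ.mean_pct_gaps_le5, 1):.1f}",
    })
    files["summary"] = out / "map_summary.tsv"
    pd.DataFrame(srows, columns=SUMMARY_HEADER).to_csv(files["summary"], sep="\t", index=False)

    files["snp_types"] = out / "snp_types.tsv"
    trows = []
    if snp_type_counts:
        ratios = summary_ratios(snp_type_counts)
        for t in ("R", "Y", "S", "W", "K", "M"):
            if t in snp_type_counts:
                trows.append({"snp_type": t, "count": snp_type_counts[t],
                              "pct": f"{ratios[t]:.1f}"})
    pd.DataFrame(trows, columns=SNP_TYPE_HEADER).to_csv(files["snp_types"], sep="\t", index=False)

    files["distortion"] = out / "distortion.tsv"
    drows = []
    if distorted is not None:
        sdrs = sdrs or []
        for g in groups:
            n_dist = sum(bool(distorted.get(m, False)) for m in g.marker_ids)
            n_tot = len(g.marker_ids)
            drows.append({
                "lg": g.lg_id, "n_markers": n_tot, "n_distorted": n_dist,
                "pct_distorted": f"{percent(n_dist, n_tot):.1f}" if n_tot else "",
                "n_sdr": sum(1 for s in sdrs if s.lg_id == g.lg_id),
            })
    pd.DataFrame(drows, columns=DISTORTION_HEADER).to_csv(files["distortion"], sep="\t", index=False)

    files["manifest"] = out / "manifest.json"
    with open(files["manifest"], "w") as fh:
        json.dump(manifest or {}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return files
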