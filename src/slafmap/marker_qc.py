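"""Marker-level quality filters and the segregation chi-square test.

Filters are applied in a fixed order — depth, then missingness, then the
1:2:1 chi-square test — and split the surviving markers into a framework
set (Mendelian segregation) used to build the map and an accessory set
(significantly distorted, p < 0.05) inserted afterwards.  No
multiple-testing correction is applied to the chi-square p-values; the raw
0.05 threshold is the field's convention for flagging distorted markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_calling import GenotypeMatrix, AA, AB, BB, MISSING

__all__ = ["QcConfig", "QcResult", "chi_square_121", "apply_filters"]


@dataclass(frozen=True)
class QcConfig:
    """Thresholds for marker-level QC.

    Parent depth must exceed ``min_parent_depth`` (fold, averaged over the
    two parents) and mean progeny depth ``min_progeny_depth``; markers with
    more than ``max_missing`` missing calls are dropped; chi-square at
    ``alpha`` flags distortion.
    """

    min_parent_depth: float = 29.0
    min_progeny_depth: float = 3.0
    max_missing: float = 0.30
    alpha: float = 0.05


@dataclass(frozen=True)
class QcResult:
    marker_id: str
    mean_parent_depth: float
    mean_progeny_depth: float
    missing_fraction: float
    chi2: float
    p_value: float
    verdict: str  # framework / accessory_distorted / filtered_missing / filtered_depth


def chi_square_121(n_aa: int, n_ab: int, n_bb: int) -> tuple[float, int, float]:
    """Chi-square test of the F2 Mendelian 1:2:1 genotype ratio.

    Expected counts are (n/4, n/2, n/4); the statistic has 2 degrees of
    freedom (no continuity correction).  Returns (chi2, df, p).

    >>> chi_square_121(25, 50, 25)
    (0.0, 2, 1.0)
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("chi-square of 1:2:1 undefined for zero total count")
    expected = n * np.array([0.25, 0.5, 0.25])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=2))
    return chi2, 2, p


def chi_square_121_matrix(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized 1:2:1 test per row of a (markers x individuals) code matrix."""
    counts = np.stack([(codes == g).sum(axis=1) for g in (AA, AB, BB)], axis=1).astype(float)
    n = counts.sum(axis=1)
    expected = n[:, None] * np.array([0.25, 0.5, 0.25])
    with np.errstate(invalid="ignore", divide="ignore"):
        chi2 = np.sum((counts - expected) ** 2 / expected, axis=1)
    chi2 = np.where(n > 0, chi2, np.nan)
    p = stats.chi2.sf(chi2, df=2)
    return chi2, p


def apply_filters(matrix: GenotypeMatrix,
                  parent_depth: pd.Series | None = None,
                  config: QcConfig = QcConfig()) -> tuple[list[QcResult], dict]:
    """Run the QC cascade and partition markers.

    Parameters
    ----------
    matrix
        Called progeny genotypes with depth metadata (progeny columns only).
    parent_depth
        Per-marker mean parental depth (fold).  ``None`` skips the parent
        side of the depth filter (e.g. when parents were not sequenced).
    config
        Thresholds; defaults are parents > 29-fold, progeny > 3-fold,
        missing <= 30%, alpha = 0.05.

    Returns
    -------
    (results, partition)
        One :class:`QcResult` per marker, and a dict with marker-id lists
        under 'framework', 'accessory', 'filtered_depth', 'filtered_missing'.

    Raises
    ------
    RuntimeError
        If no marker survives the cascade.
    """
    codes = matrix.codes.to_numpy()
    depth = matrix.depth.to_numpy(dtype=float)
    n_ind = codes.shape[1]
    missing_frac = (codes == MISSING).sum(axis=1) / n_ind
    progeny_depth = depth.mean(axis=1)
    chi2_all, p_all = chi_square_121_matrix(codes)

    results: list[QcResult] = []
    partition: dict[str, list] = {
        "framework": [], "accessory": [], "filtered_depth": [], "filtered_missing": []
    }
    for i, mid in enumerate(matrix.marker_ids):
        pdep = float(parent_depth[mid]) if parent_depth is not None else np.inf
        if pdep <= config.min_parent_depth or progeny_depth[i] <= config.min_progeny_depth:
            verdict = "filtered_depth"
        elif missing_frac[i] > config.max_missing:
            verdict = "filtered_missing"
        elif np.isnan(p_all[i]):
            verdict = "filtered_missing"
        elif p_all[i] < config.alpha:
            verdict = "accessory_distorted"
        else:
            verdict = "framework"
        results.append(QcResult(
            marker_id=mid,
            mean_parent_depth=pdep if np.isfinite(pdep) else float("nan"),
            mean_progeny_depth=float(progeny_depth[i]),
            missing_fraction=float(missing_frac[i]),
            chi2=float(chi2_all[i]) if not np.isnan(chi2_all[i]) else float("nan"),
            p_value=float(p_all[i]) if not np.isnan(p_all[i]) else float("nan"),
            verdict=verdict,
        ))
        key = {"framework": "framework", "accessory_distorted": "accessory",
               "filtered_depth": "filtered_depth",
               "filtered_missing": "filtered_missing"}[verdict]
        partition[key].append(mid)

    if not partition["framework"] and not partition["accessory"]:
        raise RuntimeError("QC removed every marker; check depth/missing thresholds")
    return results, partition


def qc_table(results: list[QcResult]) -> pd.DataFrame:
    """QC report as a tab-writable table."""
    return pd.DataFrame([r.__dict__ for r in results])
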