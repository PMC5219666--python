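"""Bayesian genotype scoring from allele read counts.

Each F2 individual at each fully informative (aa x bb) marker is scored
from its two allele read counts.  Reads are treated as independent
Bernoulli draws: an aa individual yields an A read with probability
1 - epsilon, a bb individual with probability epsilon, and a heterozygote
with probability 1/2 (a sequencing error swaps the alleles, leaving the
heterozygote likelihood unchanged).  The posterior over {aa, ab, bb} uses
the F2 prior 1:2:1 by default, and the call is the posterior mode.  The
quality score is a phred-like transform of the posterior, capped so it
remains bounded and comparable across depths.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GenotypeCall", "GenotypeMatrix", "genotype_posterior",
           "call_matrix", "iterative_quality_prune"]

AA, AB, BB, MISSING = 0, 1, 2, -1
GENO_LABELS = {0: "aa", 1: "ab", 2: "bb", -1: "--"}

F2_PRIOR = (0.25, 0.5, 0.25)
QUALITY_CAP = 60.0


@dataclass(frozen=True)
class GenotypeCall:
    genotype: int  # 0 aa, 1 ab, 2 bb, -1 missing
    posterior: float
    quality: float
    depth: int

    @property
    def label(self) -> str:
        return GENO_LABELS[self.genotype]


@dataclass
class GenotypeMatrix:
    """Called genotypes with per-call quality and depth side channels.

    ``codes`` is a (markers x individuals) int8 DataFrame with entries in
    {0, 1, 2, -1}; ``quality`` and ``depth`` share its axes.
    """

    codes: pd.DataFrame
    quality: pd.DataFrame
    depth: pd.DataFrame

    @property
    def marker_ids(self) -> list:
        return list(self.codes.index)

    @property
    def individuals(self) -> list:
        return list(self.codes.columns)

    def integrity(self) -> pd.Series:
        """Per-marker fraction of non-missing calls."""
        return (self.codes != MISSING).mean(axis=1)

    def to_labels(self) -> pd.DataFrame:
        return self.codes.replace(GENO_LABELS)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.codes.copy(), self.quality.copy(), self.depth.copy())


def _posteriors(count_a: np.ndarray, count_b: np.ndarray, error_rate: float,
                priors: tuple) -> np.ndarray:
    """Posterior P(genotype | counts) with shape (..., 3)."""
    ca = np.asarray(count_a, dtype=float)
    cb = np.asarray(count_b, dtype=float)
    log_e = np.log(error_rate)
    log_1e = np.log1p(-error_rate)
    log_half = np.log(0.5)
    ll = np.stack(
        [
            ca * log_1e + cb * log_e,
            (ca + cb) * log_half,
            ca * log_e + cb * log_1e,
        ],
        axis=-1,
    )
    ll += np.log(np.asarray(priors, dtype=float))
    ll -= ll.max(axis=-1, keepdims=True)
    w = np.exp(ll)
    return w / w.sum(axis=-1, keepdims=True)


def _quality(posterior: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        q = -10.0 * np.log10(np.maximum(1.0 - posterior, 0.0))
    return np.minimum(q, QUALITY_CAP)


def genotype_likelihoods(count_a: pd.DataFrame | np.ndarray,
                         count_b: pd.DataFrame | np.ndarray,
                         error_rate: float = 0.01) -> np.ndarray:
    """Normalized genotype likelihoods P(reads | genotype), shape (m, n, 3).

    The soft counterpart of hard calling: zero-depth cells get the
    uninformative vector (1/3, 1/3, 1/3), a single read leans toward the
    matching homozygote without excluding the heterozygote, and deep
    cells approach certainty.  Downstream linkage estimation can consume
    these directly, which keeps every read informative at shallow depth.
    """
    ca = np.asarray(count_a, dtype=float)
    cb = np.asarray(count_b, dtype=float)
    ll = np.stack(
        [
            ca * np.log1p(-error_rate) + cb * np.log(error_rate),
            (ca + cb) * np.log(0.5),
            ca * np.log(error_rate) + cb * np.log1p(-error_rate),
        ],
        axis=-1,
    )
    ll -= ll.max(axis=-1, keepdims=True)
    w = np.exp(ll)
    return w / w.sum(axis=-1, keepdims=True)


def genotype_posterior(count_a: int, count_b: int, error_rate: float = 0.01,
                       priors: tuple = F2_PRIOR) -> GenotypeCall:
    """Score one individual at one marker from its allele read counts.

    Returns a missing call (quality 0) when both counts are zero.

    >>> genotype_posterior(5, 0, 0.01).label
    'aa'
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("read counts must be non-negative")
    if not (0.0 < error_rate < 0.5):
        raise ValueError("error_rate must lie in (0, 0.5)")
    depth = int(count_a) + int(count_b)
    if depth == 0:
        return GenotypeCall(MISSING, np.nan, 0.0, 0)
    post = _posteriors(count_a, count_b, error_rate, priors)
    g = int(np.argmax(post))
    return GenotypeCall(g, float(post[g]), float(_quality(post[g])), depth)


def call_matrix(count_a: pd.DataFrame, count_b: pd.DataFrame,
                error_rate: float = 0.01, priors: tuple = F2_PRIOR,
                min_posterior: float = 0.0) -> GenotypeMatrix:
    """Vectorized genotype calling over a (markers x individuals) count pair.

    ``min_posterior`` optionally masks calls whose posterior falls below the
    threshold (0 disables the mask, keeping every non-zero-depth call).
    """
    if not count_a.index.equals(count_b.index) or not count_a.columns.equals(count_b.columns):
        raise ValueError("count_a and count_b must share axes")
    ca = count_a.to_numpy(dtype=float)
    cb = count_b.to_numpy(dtype=float)
    depth = (ca + cb).astype(int)
    post = _posteriors(ca, cb, error_rate, priors)
    g = np.argmax(post, axis=-1).astype(np.int8)
    best = np.take_along_axis(post, g[..., None].astype(int), axis=-1)[..., 0]
    q = _quality(best)
    missing = depth == 0
    if min_posterior > 0:
        missing |= best < min_posterior
    g[missing] = MISSING
    q[missing] = 0.0
    return GenotypeMatrix(
        codes=pd.DataFrame(g, index=count_a.index, columns=count_a.columns, dtype=np.int8),
        quality=pd.DataFrame(q, index=count_a.index, columns=count_a.columns),
        depth=pd.DataFrame(depth, index=count_a.index, columns=count_a.columns),
    )


def iterative_quality_prune(matrix: GenotypeMatrix, gq_cutoff: float,
                            min_markers: int = 1, min_individuals: int = 1
                            ) -> tuple[GenotypeMatrix, list[dict]]:
    """Dynamic quality pruning: drop the worst marker or individual until
    the mean genotype quality of the matrix reaches the cutoff.

    Missing calls contribute quality 0 to the means, so a sparse marker is
    low quality by construction.  Each removal is logged with the offending
    axis, identifier and its mean quality.

    Raises
    ------
    RuntimeError
        If the cutoff cannot be reached before the matrix shrinks below
        ``min_markers`` x ``min_individuals``.
    """
    mat = matrix.copy()
    log: list[dict] = []
    while True:
        overall = float(mat.quality.to_numpy().mean()) if mat.quality.size else 0.0
        if overall >= gq_cutoff:
            return mat, log
        if len(mat.marker_ids) <= min_markers and len(mat.individuals) <= min_individuals:
            raise RuntimeError(
                f"quality cutoff {gq_cutoff} unreachable: matrix reduced to "
                f"{len(mat.marker_ids)} markers x {len(mat.individuals)} individuals "
                f"at mean quality {overall:.2f}"
            )
        marker_means = mat.quality.mean(axis=1)
        indiv_means = mat.quality.mean(axis=0)
        worst_marker = marker_means.idxmin()
        worst_indiv = indiv_means.idxmin()
        drop_marker = (
            marker_means[worst_marker] <= indiv_means[worst_indiv]
            and len(mat.marker_ids) > min_markers
        ) or len(mat.individuals) <= min_individuals
        if drop_marker:
            log.append({"axis": "marker", "id": worst_marker,
                        "mean_quality": float(marker_means[worst_marker])})
            keep = mat.codes.index != worst_marker
            mat = GenotypeMatrix(mat.codes.loc[keep], mat.quality.loc[keep], mat.depth.loc[keep])
        else:
            log.append({"axis": "individual", "id": worst_indiv,
                        "mean_quality": float(indiv_means[worst_indiv])})
            keep = mat.codes.columns != worst_indiv
            mat = GenotypeMatrix(
                mat.codes.loc[:, keep], mat.quality.loc[:, keep], mat.depth.loc[:, keep]
            )
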