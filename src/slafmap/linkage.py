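"""Two-point linkage analysis for codominant F2 markers.

Recombination fractions between marker pairs are estimated by maximum
likelihood (EM) from 3x3 joint genotype tables, LOD scores are computed as
the log10 likelihood ratio against free recombination (r = 0.5), and markers
are partitioned into linkage groups by single-linkage transitive closure on
a modified-LOD (MLOD) threshold.

Model
-----
Both parents are fully homozygous, so every informative marker segregates
aa : ab : bb = 1 : 2 : 1 in the F2.  For two linked markers in coupling
phase the nine joint genotype classes have the classical probabilities in
terms of the recombination fraction r (c = 1 - r):

    =====  =========  =========  =========
            aa          ab          bb
    aa      c^2/4       cr/2        r^2/4
    ab      cr/2      (c^2+r^2)/2   cr/2
    bb      r^2/4       cr/2        c^2/4
    =====  =========  =========  =========

The double heterozygote class is a mixture of parental (c^2) and
recombinant (r^2) two-gamete origins; EM resolves the mixture by its
expected recombinant-gamete count each iteration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "TwoPointResult",
    "GroupingResult",
    "transition_matrix",
    "joint_class_probs",
    "estimate_r_em",
    "lod_score",
    "pairwise_r_lod",
    "group_markers",
]

# genotype codes used throughout the package
AA, AB, BB, MISSING = 0, 1, 2, -1

#: recombinant gametes contributed by each joint class (double het handled
#: separately as a mixture of 0 and 2)
_RECOMB_COUNT = np.array(
    [[0.0, 1.0, 2.0],
     [1.0, np.nan, 1.0],
     [2.0, 1.0, 0.0]]
)

R_MIN = 1e-7


@dataclass(frozen=True)
class TwoPointResult:
    """ML estimate of the recombination fraction for one marker pair."""

    r_hat: float
    lod: float
    n_informative: int
    phase: str = "coupling"  # phase with the higher maximized likelihood


@dataclass
class GroupingResult:
    """Partition of markers into linkage groups."""

    groups: list[list[int]]
    unlinked: list[int]
    threshold: float = 5.0

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def transition_matrix(r: float) -> np.ndarray:
    """Markov transition P(genotype at next locus | genotype here).

    The two gametes of an F2 individual are independent two-state chains,
    which makes the genotype process along a chromosome Markov with

        aa -> (c^2, 2rc, r^2),  ab -> (rc, c^2 + r^2, rc),  bb mirrored,

    where c = 1 - r.  Rows sum to 1; the stationary law is (1/4, 1/2, 1/4).
    """
    c = 1.0 - r
    return np.array(
        [
            [c * c, 2.0 * r * c, r * r],
            [r * c, c * c + r * r, r * c],
            [r * r, 2.0 * r * c, c * c],
        ]
    )


def joint_class_probs(r: float) -> np.ndarray:
    """3x3 joint genotype probabilities for a coupling-phase F2 pair."""
    pi = np.array([0.25, 0.5, 0.25])
    return pi[:, None] * transition_matrix(r)


def _em_r(table: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> float:
    """EM iteration for r on one 3x3 count table (counts may be fractional)."""
    n = table.sum()
    if n <= 0:
        return float("nan")
    known = np.nansum(_RECOMB_COUNT * table)
    n_dh = table[1, 1]
    r = 0.25
    for _ in range(max_iter):
        c = 1.0 - r
        w = r * r / (c * c + r * r) if (c * c + r * r) > 0 else 0.0
        r_new = (known + 2.0 * w * n_dh) / (2.0 * n)
        r_new = min(max(r_new, R_MIN), 0.5)
        if abs(r_new - r) < tol:
            return r_new
        r = r_new
    return r


def _loglik(table: np.ndarray, r: float) -> float:
    """Multinomial log10-likelihood (up to the combinatorial constant)."""
    p = np.maximum(joint_class_probs(r), 1e-300)
    return float(np.sum(table * np.log10(p)))


def lod_score(table: np.ndarray, r_hat: float) -> float:
    """LOD = log10 L(r_hat) - log10 L(0.5) under the joint class model."""
    table = np.asarray(table, dtype=float)
    return max(_loglik(table, r_hat) - _loglik(table, 0.5), 0.0)


def estimate_r_em(table: np.ndarray) -> TwoPointResult:
    """Estimate r for one marker pair from a 3x3 joint genotype count table.

    Rows index the first marker's genotypes (aa, ab, bb), columns the
    second's.  Both linkage phases are evaluated (repulsion corresponds to
    swapping the homozygote labels at one marker); the phase with the higher
    maximized likelihood is retained, so the estimate is invariant to allele
    relabelling.

    Parameters
    ----------
    table
        Non-negative counts; individuals with a missing genotype at either
        marker must already be excluded.

    Raises
    ------
    ValueError
        If the table is empty (no informative individuals).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (3, 3):
        raise ValueError(f"expected a 3x3 table, got shape {table.shape}")
    n = int(round(table.sum()))
    if n == 0:
        raise ValueError("no informative individuals: empty genotype table")

    r_c = _em_r(table)
    flipped = table[:, ::-1]
    r_r = _em_r(flipped)
    ll_c = _loglik(table, r_c)
    ll_r = _loglik(flipped, r_r)
    if ll_r > ll_c:
        return TwoPointResult(
            r_hat=r_r, lod=lod_score(flipped, r_r), n_informative=n, phase="repulsion"
        )
    return TwoPointResult(
        r_hat=r_c, lod=lod_score(table, r_c), n_informative=n, phase="coupling"
    )


def _joint_count_tables(codes: np.ndarray) -> np.ndarray:
    """All pairwise 3x3 tables from a (markers x individuals) code matrix.

    Returns an array of shape (m, m, 3, 3); missing genotypes (-1) are
    excluded pairwise.
    """
    ind = np.stack([(codes == g).astype(float) for g in (AA, AB, BB)])
    tables = np.einsum("gmi,hni->mngh", ind, ind)
    return tables


def _joint_probs_batch(r: np.ndarray) -> np.ndarray:
    """Joint 3x3 class probabilities for a vector of r values: (len(r), 3, 3)."""
    c = 1.0 - r
    pi = np.array([0.25, 0.5, 0.25])
    t = np.empty((len(r), 3, 3))
    t[:, 0, 0] = c * c
    t[:, 0, 1] = 2 * r * c
    t[:, 0, 2] = r * r
    t[:, 1, 0] = r * c
    t[:, 1, 1] = c * c + r * r
    t[:, 1, 2] = r * c
    t[:, 2, 0] = r * r
    t[:, 2, 1] = 2 * r * c
    t[:, 2, 2] = c * c
    return pi[None, :, None] * t


def pairwise_r_lod(
    codes: np.ndarray, tol: float = 1e-8, max_iter: int = 500,
    obs_error: float = 0.0, margin_adjusted: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized two-point analysis over all marker pairs.

    Parameters
    ----------
    codes
        int matrix (markers x individuals) with entries in {0, 1, 2, -1}
        for {aa, ab, bb, missing}.
    obs_error
        Optional genotype miscall rate: when > 0, the latent true joint
        genotypes are estimated through a symmetric miscall emission
        (probability ``obs_error`` split over the two wrong genotypes),
        which de-biases r upward-contaminated by isolated miscalls.  0
        gives the plain class model.
    margin_adjusted
        When True the returned LOD is the modified (margin-corrected) LOD:
        the linkage likelihood is scored against an independence baseline
        with the pair's *empirical* genotype margins rather than the
        Mendelian 1:2:1.  Two unlinked markers that are both
        segregation-distorted then score ~0 instead of showing spurious
        linkage, which makes this the grouping statistic of choice.

    Returns
    -------
    (r, lod, n_informative)
        Symmetric (m x m) matrices.  Diagonals are r = 0, lod = 0.  The
        higher-likelihood phase is chosen per pair, as in
        :func:`estimate_r_em`.
    """
    codes = np.asarray(codes)
    m = codes.shape[0]
    tables = _joint_count_tables(codes)  # (m, m, 3, 3)
    flat = tables.reshape(m * m, 3, 3)
    err = np.full((3, 3), obs_error / 2.0)
    np.fill_diagonal(err, 1.0 - obs_error)

    def em_all(tabs: np.ndarray) -> np.ndarray:
        n = tabs.sum(axis=(1, 2))
        safe_n = np.where(n > 0, n, 1.0)
        r = np.full(tabs.shape[0], 0.25)
        if obs_error == 0.0:
            known = np.nansum(_RECOMB_COUNT[None, :, :] * tabs, axis=(1, 2))
            n_dh = tabs[:, 1, 1]
            for _ in range(max_iter):
                c = 1.0 - r
                denom = c * c + r * r
                w = np.where(denom > 0, r * r / np.where(denom > 0, denom, 1.0), 0.0)
                r_new = np.clip((known + 2.0 * w * n_dh) / (2.0 * safe_n), R_MIN, 0.5)
                if np.max(np.abs(r_new - r)) < tol:
                    return np.where(n > 0, r_new, np.nan)
                r = r_new
            return np.where(n > 0, r, np.nan)
        rec = np.nan_to_num(_RECOMB_COUNT, nan=0.0)
        for _ in range(max_iter):
            p_true = _joint_probs_batch(r)
            p_obs = np.einsum("pkl,ki,lj->pij", p_true, err, err)
            ratio = tabs / np.maximum(p_obs, 1e-300)
            latent = p_true * np.einsum("pij,ki,lj->pkl", ratio, err, err)
            known = np.einsum("pkl,kl->p", latent, rec)
            n_dh = latent[:, 1, 1]
            c = 1.0 - r
            denom = c * c + r * r
            w = np.where(denom > 0, r * r / np.where(denom > 0, denom, 1.0), 0.0)
            r_new = np.clip((known + 2.0 * w * n_dh) / (2.0 * safe_n), R_MIN, 0.5)
            if np.max(np.abs(r_new - r)) < tol:
                return np.where(n > 0, r_new, np.nan)
            r = r_new
        return np.where(n > 0, r, np.nan)

    def ll_all(tabs: np.ndarray, r: np.ndarray) -> np.ndarray:
        p = _joint_probs_batch(r)
        if obs_error > 0.0:
            p = np.einsum("pkl,ki,lj->pij", p, err, err)
        return np.sum(tabs * np.log10(np.maximum(p, 1e-300)), axis=(1, 2))

    flat_flip = flat[:, :, ::-1]
    r_c = em_all(flat)
    r_r = em_all(flat_flip)
    with np.errstate(invalid="ignore"):
        safe_rc = np.where(np.isnan(r_c), 0.25, r_c)
        safe_rr = np.where(np.isnan(r_r), 0.25, r_r)
        ll_c = ll_all(flat, safe_rc)
        ll_r = ll_all(flat_flip, safe_rr)
        ll_null_c = ll_all(flat, np.full(len(flat), 0.5))
        use_rep = ll_r > ll_c
        r_hat = np.where(use_rep, r_r, r_c)
        ll_null = ll_null_c
        if margin_adjusted:
            rows = flat.sum(axis=2)
            cols = flat.sum(axis=1)
            tot = np.maximum(flat.sum(axis=(1, 2)), 1.0)
            p_ind = rows[:, :, None] * cols[:, None, :] / (tot * tot)[:, None, None]
            ll_ind = np.sum(flat * np.log10(np.maximum(p_ind, 1e-300)), axis=(1, 2))
            ll_null = np.maximum(ll_null_c, ll_ind)
        lod = np.where(use_rep, ll_r, ll_c) - ll_null
    lod = np.maximum(lod, 0.0)

    r_mat = r_hat.reshape(m, m)
    lod_mat = lod.reshape(m, m)
    n_mat = flat.sum(axis=(1, 2)).reshape(m, m).astype(int)
    np.fill_diagonal(r_mat, 0.0)
    np.fill_diagonal(lod_mat, 0.0)
    # enforce exact symmetry (EM on T and T' can differ in the last ulp)
    r_mat = np.fmin(r_mat, r_mat.T)
    lod_mat = np.fmax(lod_mat, lod_mat.T)
    return r_mat, lod_mat, n_mat


def count_classes(count_a: np.ndarray, count_b: np.ndarray, cap: int = 3,
                  error_rate: float = 0.01) -> tuple[np.ndarray, np.ndarray]:
    """Quantize read-count cells into genotype-likelihood classes.

    Cells with both counts <= ``cap`` keep their exact (countA, countB)
    likelihood; deeper cells collapse into three near-certain classes
    (pure A, pure B, mixed), represented by (2*cap, 0), (0, 2*cap) and
    (2*cap, 2*cap).  Returns (class index matrix (m, n), class
    genotype-likelihood table (K, 3)).  The grid keeps the joint
    class-pair tables small enough for fully vectorized EM while staying
    exact where shallow-depth ambiguity actually lives.
    """
    a = np.asarray(count_a, dtype=int)
    b = np.asarray(count_b, dtype=int)
    k = cap + 1
    cls = np.minimum(a, cap) * k + np.minimum(b, cap)
    deep = 2 * cap
    pure_a = (a > cap) & (b == 0)
    pure_b = (a == 0) & (b > cap)
    # deep asymmetric cells (one stray read of the minor allele) stay
    # genuinely ambiguous and get their own classes; deeper mixtures are
    # heterozygote-certain
    edge_a = (a > cap) & (b == 1)
    edge_b = (a == 1) & (b > cap)
    mixed = ((a > cap) & (b >= 2)) | ((b > cap) & (a >= 2))
    cls = np.where(pure_a, k * k,
          np.where(pure_b, k * k + 1,
          np.where(edge_a, k * k + 2,
          np.where(edge_b, k * k + 3,
          np.where(mixed, k * k + 4, cls)))))
    grid = [(x // k, x % k) for x in range(k * k)]
    # deep-class representatives use the mean counts of their members, so
    # the classes stay faithful whether the data are 3x or 30x
    def mean_or(sel, arr, default):
        return float(arr[sel].mean()) if sel.any() else default

    grid += [
        (mean_or(pure_a, a, deep), 0.0),
        (0.0, mean_or(pure_b, b, deep)),
        (mean_or(edge_a, a, cap + 2), 1.0),
        (1.0, mean_or(edge_b, b, cap + 2)),
        (mean_or(mixed, a, deep), mean_or(mixed, b, deep)),
    ]
    a_grid = np.array([g[0] for g in grid], dtype=float)
    b_grid = np.array([g[1] for g in grid], dtype=float)
    ll = np.stack(
        [
            a_grid * np.log1p(-error_rate) + b_grid * np.log(error_rate),
            (a_grid + b_grid) * np.log(0.5),
            a_grid * np.log(error_rate) + b_grid * np.log1p(-error_rate),
        ],
        axis=-1,
    )
    ll -= ll.max(axis=-1, keepdims=True)
    w = np.exp(ll)
    class_gl = w / w.sum(axis=-1, keepdims=True)
    return cls, class_gl


def pairwise_r_lod_counts(count_a: np.ndarray, count_b: np.ndarray,
                          error_rate: float = 0.01, cap: int = 3,
                          tol: float = 1e-6, max_iter: int = 150,
                          chunk: int = 8000
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-point analysis directly from allele read counts.

    Genotypes are never hard-called: each individual contributes its
    genotype likelihood given the reads (exact under the per-read error
    model), and EM maximizes the pair likelihood over r with the latent
    joint genotypes marginalized.  At shallow depth this uses every read
    — a single read still discounts one homozygote — so r estimates are
    far less noisy and carry none of the miscall-driven upward bias of
    hard-call tables.

    Returns symmetric (m x m) matrices (r, lod, n_informative) where
    n_informative counts individuals with at least one read at both
    markers.  The better linkage phase is kept per pair.
    """
    cls, cgl = count_classes(count_a, count_b, cap=cap, error_rate=error_rate)
    m, n = cls.shape
    nk = cgl.shape[0]
    onehot = np.stack([(cls == a) for a in range(nk)]).astype(np.float32)  # (K, m, n)
    flat_oh = onehot.reshape(nk, m * n)
    # N[i, j, a, b] = #individuals in class a at marker i and class b at j
    tabs = np.empty((m, m, nk, nk), dtype=np.float32)
    for a in range(nk):
        block = onehot[a] @ onehot.reshape(nk * m, n).T  # (m, K*m)
        tabs[:, :, a, :] = block.reshape(m, nk, m).transpose(0, 2, 1)
    cgl_f = cgl.astype(np.float64)
    cgl_rev = cgl_f[:, ::-1]

    r_out = np.zeros((m, m))
    lod_out = np.zeros((m, m))
    iu = np.triu_indices(m, k=1)
    pair_tabs = tabs[iu].astype(np.float64)  # (P, K, K)
    rec = np.nan_to_num(_RECOMB_COUNT, nan=0.0)

    def w_of(tabs_or_ptrue: np.ndarray, cg2: np.ndarray) -> np.ndarray:
        # W[p, a, b] = sum_{g,h} CG1[a,g] P_true[p,g,h] CG2[b,h], via two GEMMs
        t1 = np.tensordot(tabs_or_ptrue, cg2, axes=([2], [1]))     # (P, 3, K)
        return np.tensordot(t1, cgl_f, axes=([1], [1])).transpose(0, 2, 1)

    def em_steps(tabs_p, n_p, r, n_steps, cg2, stop_tol):
        """Run up to n_steps EM updates in place; returns final step sizes."""
        step = np.full(len(r), np.inf)
        active = np.arange(len(r))
        for _ in range(n_steps):
            r_act = r[active]
            p_true = _joint_probs_batch(r_act)
            w_norm = w_of(p_true, cg2)
            ratio = tabs_p[active] / np.maximum(w_norm, 1e-300)
            # latent[p,g,h] = P_true * sum_{a,b} CG1[a,g] ratio[p,a,b] CG2[b,h]
            t1 = np.tensordot(ratio, cg2, axes=([2], [0]))          # (P, K, 3)
            back = np.tensordot(t1, cgl_f, axes=([1], [0])).transpose(0, 2, 1)
            latent = p_true * back
            known = np.einsum("pgh,gh->p", latent, rec)
            n_dh = latent[:, 1, 1]
            c = 1.0 - r_act
            denom = np.maximum(c * c + r_act * r_act, 1e-300)
            wmix = r_act * r_act / denom
            r_new = np.clip((known + 2.0 * wmix * n_dh) / (2.0 * n_p[active]),
                            R_MIN, 0.5)
            step[active] = np.abs(r_new - r_act)
            r[active] = r_new
            keep = (step[active] >= stop_tol) & (r_new < 0.4995)
            if not keep.any():
                break
            active = active[keep]
        return step

    def em(tabs_p: np.ndarray, cg2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n_tot = tabs_p.sum(axis=(1, 2))
        safe_n = np.where(n_tot > 0, n_tot, 1.0)
        r = np.full(tabs_p.shape[0], 0.25)
        # cheap first stage for every pair; unlinked pairs (r near 0.5 or
        # still drifting upward) need no precision — their LOD is ~0
        step = em_steps(tabs_p, safe_n, r, 25, cg2, tol)
        refine = (r < 0.45) & (step >= tol)
        if refine.any():
            r_ref = r[refine]
            em_steps(tabs_p[refine], safe_n[refine], r_ref, max_iter, cg2, tol)
            r[refine] = r_ref
        p_true = _joint_probs_batch(r)
        w_norm = w_of(p_true, cg2)
        ll = np.sum(tabs_p * np.log10(np.maximum(w_norm, 1e-300)), axis=(1, 2))
        return r, ll

    n_pairs = pair_tabs.shape[0]
    r_best = np.empty(n_pairs)
    lod_best = np.empty(n_pairs)
    for lo in range(0, n_pairs, chunk):
        sl = slice(lo, min(lo + chunk, n_pairs))
        tp = pair_tabs[sl]
        r_c, ll_c = em(tp, cgl_f)
        r_r, ll_r = em(tp, cgl_rev)
        p_null = _joint_probs_batch(np.full(tp.shape[0], 0.5))
        w_null = cgl_f @ p_null @ cgl_f.T
        ll_null = np.sum(tp * np.log10(np.maximum(w_null, 1e-300)), axis=(1, 2))
        use_rep = ll_r > ll_c
        r_best[sl] = np.where(use_rep, r_r, r_c)
        lod_best[sl] = np.maximum(np.where(use_rep, ll_r, ll_c) - ll_null, 0.0)

    r_out[iu] = r_best
    lod_out[iu] = lod_best
    r_out += r_out.T
    lod_out += lod_out.T
    has_reads = (np.asarray(count_a) + np.asarray(count_b)) > 0
    n_inf = (has_reads.astype(np.int32) @ has_reads.T.astype(np.int32))
    return r_out, lod_out, n_inf


def group_markers(lod_matrix: np.ndarray, mlod_threshold: float = 5.0) -> GroupingResult:
    """Partition markers into linkage groups by single-linkage closure.

    Two markers belong to the same group iff they are connected by a path of
    pairs whose MLOD is at least ``mlod_threshold``.  Markers with no
    partner at or above the threshold are reported as unlinked (these are
    the markers the MLOD < threshold filter removes).

    The MLOD used here is the two-point LOD at the ML recombination
    fraction; see docs for why this stands in for the grouping-LOD variant.
    """
    lod_matrix = np.asarray(lod_matrix, dtype=float)
    m = lod_matrix.shape[0]
    if m == 0:
        return GroupingResult(groups=[], unlinked=[], threshold=mlod_threshold)
    g = nx.Graph()
    g.add_nodes_from(range(m))
    ii, jj = np.where(np.triu(lod_matrix >= mlod_threshold, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    groups: list[list[int]] = []
    unlinked: list[int] = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) == 1:
            unlinked.append(members[0])
        else:
            groups.append(members)
    groups.sort(key=lambda grp: (-len(grp), grp[0]))
    return GroupingResult(groups=groups, unlinked=sorted(unlinked), threshold=mlod_threshold)


def correlation_lod(codes: np.ndarray, min_pairs: int = 30) -> np.ndarray:
    """Margin-robust linkage evidence per marker pair (Fisher-Z LOD scale).

    Pearson correlation of the genotype dosage codes (aa=0, ab=1, bb=2)
    over pairwise-complete observations, converted through the Fisher Z
    transform to a 1-df chi-square and expressed on the LOD scale
    (Z^2 / (2 ln 10)), so the usual grouping threshold applies.  Because
    correlation is invariant to each marker's own genotype frequencies,
    two unlinked but segregation-distorted markers score ~0 here even
    though their shared skewed margins inflate the model-based linkage
    LOD — which makes this the robust choice for partitioning markers
    into linkage groups before any distortion filtering.

    Pairs with fewer than ``min_pairs`` complete observations score 0.
    """
    codes = np.asarray(codes, dtype=float)
    obs = (codes >= 0).astype(float)
    x = np.where(codes >= 0, codes, 0.0)
    n = obs @ obs.T
    sx = x @ obs.T
    sy = sx.T
    sxy = x @ x.T
    sxx = (x * x) @ obs.T
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        var = (n * sxx - sx * sx) * (n * syy - sy * sy)
        rho = cov / np.sqrt(np.maximum(var, 1e-300))
    rho = np.clip(np.nan_to_num(rho), -0.999999, 0.999999)
    z = np.arctanh(rho) * np.sqrt(np.maximum(n - 3.0, 0.0))
    lod = (z * z) / (2.0 * np.log(10.0))
    lod[n < min_pairs] = 0.0
    np.fill_diagonal(lod, 0.0)
    return lod


def group_markers_robust(lod_matrix: np.ndarray, mlod_threshold: float = 5.0,
                         attach_max_size: int = 2,
                         strong_single_lod: float | None = None) -> GroupingResult:
    """Single-linkage grouping hardened against chance edges.

    With tens of thousands of marker pairs, an occasional unlinked pair
    reaches the MLOD threshold by chance and a plain transitive closure
    then welds two chromosomes together.  A genuine chromosome at working
    marker density is redundantly connected (adjacent pairs plus
    skip-one pairs), so this variant only unites markers lying in the
    same 2-edge-connected component — a single bridging edge never merges
    two sizeable groups.  Small fragments (``attach_max_size`` markers or
    fewer, e.g. a chromosome-end marker hanging off one edge) are then
    attached across bridges to their best-linked neighbour group.
    """
    lod_matrix = np.asarray(lod_matrix, dtype=float)
    m = lod_matrix.shape[0]
    if m == 0:
        return GroupingResult(groups=[], unlinked=[], threshold=mlod_threshold)
    g = nx.Graph()
    g.add_nodes_from(range(m))
    ii, jj = np.where(np.triu(lod_matrix >= mlod_threshold, k=1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [set(c) for c in nx.k_edge_components(g, k=2)]
    comp_of = {}
    for ci, c in enumerate(comps):
        for node in c:
            comp_of[node] = ci
    if strong_single_lod is not None:
        # a single but overwhelming edge is also accepted as a merge: the
        # chance of such an edge between unlinked markers is negligible
        for u, v in g.edges:
            if lod_matrix[u, v] >= strong_single_lod and comp_of[u] != comp_of[v]:
                ci, cj = comp_of[u], comp_of[v]
                comps[ci] |= comps[cj]
                for node in comps[cj]:
                    comp_of[node] = ci
                comps[cj] = set()
    # attach small fragments across single edges, best LOD first
    changed = True
    while changed:
        changed = False
        sizes = {ci: len(c) for ci, c in enumerate(comps)}
        for ci, c in enumerate(comps):
            if not c or len(c) > attach_max_size:
                continue
            best, best_lod = None, 0.0
            for u in c:
                for v in g.neighbors(u):
                    cj = comp_of[v]
                    if cj != ci and lod_matrix[u, v] > best_lod:
                        best, best_lod = cj, lod_matrix[u, v]
            if best is not None:
                comps[best] |= c
                for node in c:
                    comp_of[node] = best
                comps[ci] = set()
                changed = True
    groups, unlinked = [], []
    for c in comps:
        if not c:
            continue
        members = sorted(c)
        if len(members) == 1:
            unlinked.append(members[0])
        else:
            groups.append(members)
    groups.sort(key=lambda grp: (-len(grp), grp[0]))
    return GroupingResult(groups=groups, unlinked=sorted(unlinked),
                          threshold=mlod_threshold)


def group_markers_plateau(lod_matrix: np.ndarray,
                          thresholds: np.ndarray | None = None,
                          min_group_size: int = 2,
                          robust: bool = True) -> GroupingResult:
    """Threshold-stable grouping: pick the partition that persists longest.

    Single-linkage partitions are computed over a ladder of MLOD
    thresholds; the partition (ignoring unlinked singletons) that is
    identical over the widest consecutive threshold window is returned,
    with ties going to the higher-threshold window.  This guards against
    both failure modes of a fixed cutoff — a chance between-chromosome
    pair just above it (a false merge) and a weak within-chromosome link
    just below it (a false split) — because the true chromosome partition
    is typically stable over a wide band of thresholds.
    """
    if thresholds is None:
        thresholds = np.arange(3.0, 12.01, 0.5)
    grouper = group_markers_robust if robust else group_markers
    results = [grouper(lod_matrix, float(t)) for t in thresholds]
    keys = [frozenset(frozenset(g) for g in res.groups if len(g) >= min_group_size)
            for res in results]
    best_len, best_start = 0, len(keys) - 1
    i = 0
    while i < len(keys):
        j = i
        while j + 1 < len(keys) and keys[j + 1] == keys[i]:
            j += 1
        if j - i + 1 >= best_len:  # >= prefers the later (higher) window
            best_len, best_start = j - i + 1, i
        i = j + 1
    return results[best_start + best_len - 1]


def group_by_position(chrom_of_marker: list) -> GroupingResult:
    """Alternative grouping by known genomic location (one group per chromosome).

    Used when true positions are available (e.g. simulated data with a
    reference); mirrors grouping markers by their genome locations with the
    MLOD screen as a confirmation step rather than the primary partition.
    """
    by_chrom: dict = {}
    for idx, chrom in enumerate(chrom_of_marker):
        by_chrom.setdefault(chrom, []).append(idx)
    groups = [sorted(v) for _, v in sorted(by_chrom.items())]
    return GroupingResult(groups=groups, unlinked=[], threshold=float("nan"))
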