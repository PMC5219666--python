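"""Synthetic SLAF-seq F2 datasets with ground truth.

Emulates the data-generating process the pipeline assumes: two fully
homozygous parents differing at a configurable fraction of loci, an F2
population formed by selfing their F1, shallow shotgun sequencing of a
reduced-representation tag at each locus, and gamete- or zygote-viability
selection at chosen loci to create segregation distortion.

Meiosis uses a Poisson/no-interference crossover process (crossover count
~ Poisson(length in Morgans), positions uniform), i.e. the Haldane model.
Read depth is Poisson by default with an optional negative-binomial
dispersion knob; each read reports the true allele with probability
1 - seq_error_rate.  Missing data arise from zero depth plus an explicit
masking rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "DistortionLocus", "TruthSet", "SimulatedReads",
           "simulate_meioses", "simulate_reads", "simulate_dataset"]

_BASES = np.array(list("ACGT"))
# transitions: A<->G, C<->T
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

AA, AB, BB, MISSING = 0, 1, 2, -1
GENO_LABELS = {0: "aa", 1: "ab", 2: "bb", -1: "--"}

# Default per-chromosome map lengths (cM) and marker counts follow the
# 10-chromosome sorghum F2 map this package models: total 2158.1 cM.
DEFAULT_CHROM_LENGTHS = (238.7, 287.9, 286.7, 300.4, 183.7,
                         175.0, 266.3, 134.6, 152.2, 132.8)
DEFAULT_MARKERS_PER_CHROM = (200, 292, 250, 315, 218, 216, 217, 189, 123, 226)


@dataclass(frozen=True)
class DistortionLocus:
    """A viability-selection locus causing segregation distortion.

    ``s`` is the selection coefficient in [0, 1]: a gamete (or zygote, per
    copy, under mechanism='zygote') carrying the non-selected allele is
    eliminated with probability ``s``.  ``selected_allele`` is 'a' (the
    maternal allele) or 'b'.
    """

    chromosome: int
    position_cM: float
    s: float
    selected_allele: str = "a"

    def __post_init__(self):
        if not (0.0 <= self.s <= 1.0):
            raise ValueError(f"selection coefficient s={self.s} outside [0, 1]")
        if self.selected_allele not in ("a", "b"):
            raise ValueError("selected_allele must be 'a' or 'b'")
        if not np.isfinite(self.position_cM):
            raise ValueError("distortion locus position must be finite")


@dataclass
class SimConfig:
    """Configuration of one synthetic F2 SLAF-seq experiment.

    Defaults follow the sorghum study design this package emulates:
    130 F2 individuals, 10 chromosomes with the mapped per-chromosome
    lengths and marker counts, parent tag depths of 12.9x (maternal) and
    16.8x (paternal), offspring depth 2.8x, and a 12% parent-polymorphism
    rate among simulated loci.
    """

    n_chromosomes: int = 10
    chrom_lengths_cM: tuple = DEFAULT_CHROM_LENGTHS
    markers_per_chrom: tuple = DEFAULT_MARKERS_PER_CHROM
    n_individuals: int = 130
    parent_depth_mean: tuple = (12.9, 16.8)  # (maternal, paternal) fold
    offspring_depth_mean: float = 2.8
    seq_error_rate: float = 0.01
    missing_extra_rate: float = 0.1
    distortion_loci: tuple = ()
    distortion_mechanism: str = "gamete"  # or "zygote"
    polymorphic_fraction: float = 0.12
    depth_dispersion: float = 0.0  # 0 => Poisson; >0 => NB with this 1/size
    tag_length: int = 100
    ts_tv_ratio: float = 2.0
    indel_fraction: float = 0.004  # loci whose variant includes an indel
    marker_positions: tuple | None = None  # per-chromosome cM arrays; None => uniform
    seed: int = 0

    def __post_init__(self):
        self.chrom_lengths_cM = tuple(float(x) for x in self.chrom_lengths_cM)[: self.n_chromosomes]
        self.markers_per_chrom = tuple(int(x) for x in self.markers_per_chrom)[: self.n_chromosomes]
        if len(self.chrom_lengths_cM) != self.n_chromosomes:
            raise ValueError("chrom_lengths_cM must have one entry per chromosome")
        if len(self.markers_per_chrom) != self.n_chromosomes:
            raise ValueError("markers_per_chrom must have one entry per chromosome")
        if any(not np.isfinite(l) or l < 0 for l in self.chrom_lengths_cM):
            raise ValueError("chromosome lengths must be finite and >= 0 cM")
        if any(m < 1 for m in self.markers_per_chrom):
            raise ValueError("each chromosome needs at least one marker")
        if isinstance(self.parent_depth_mean, (int, float)):
            self.parent_depth_mean = (float(self.parent_depth_mean),) * 2
        for p in (self.seq_error_rate, self.missing_extra_rate, self.polymorphic_fraction):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.distortion_mechanism not in ("gamete", "zygote"):
            raise ValueError("distortion_mechanism must be 'gamete' or 'zygote'")
        self.distortion_loci = tuple(
            d if isinstance(d, DistortionLocus) else DistortionLocus(*d)
            for d in self.distortion_loci
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distortion_loci"] = [asdict(x) for x in self.distortion_loci]
        if self.marker_positions is not None:
            d["marker_positions"] = [[float(p) for p in c] for c in self.marker_positions]
        return d


@dataclass
class TruthSet:
    """Simulator ground truth for recovery testing.

    ``positions`` has one row per marker (marker_id, chrom, cM,
    polymorphic); ``genotypes`` is markers x individuals with codes
    {0: aa, 1: ab, 2: bb} before any sequencing noise.
    """

    positions: pd.DataFrame
    genotypes: pd.DataFrame
    distortion_loci: tuple
    config: SimConfig

    @property
    def marker_ids(self) -> list[str]:
        return list(self.positions["marker_id"])

    def polymorphic_ids(self) -> list[str]:
        return list(self.positions.loc[self.positions["polymorphic"], "marker_id"])


@dataclass
class SimulatedReads:
    """Per-marker allele read counts plus the underlying tag sequences.

    ``count_a``/``count_b`` are (markers x samples) DataFrames whose first
    two columns are the parents ('P1' maternal, 'P2' paternal) followed by
    the F2 individuals.  ``loci`` carries the two allele tag sequences of
    each locus (identical for non-polymorphic loci).
    """

    count_a: pd.DataFrame
    count_b: pd.DataFrame
    loci: pd.DataFrame

    @property
    def individuals(self) -> list[str]:
        return [c for c in self.count_a.columns if not c.startswith("P")]


def _sample_gamete_alleles(
    rng: np.random.Generator, length_cM: float, positions_cM: np.ndarray
) -> np.ndarray:
    """One gamete: allele (0 = maternal, 1 = paternal) at each position."""
    start = rng.integers(0, 2)
    n_xo = rng.poisson(length_cM / 100.0)
    if n_xo == 0:
        return np.full(positions_cM.shape, start, dtype=np.int8)
    xo = np.sort(rng.uniform(0.0, length_cM, size=n_xo))
    crossings = np.searchsorted(xo, positions_cM, side="right")
    return ((start + crossings) % 2).astype(np.int8)


def _viable_gamete(
    rng: np.random.Generator,
    length_cM: float,
    positions_cM: np.ndarray,
    sel_pos: np.ndarray,
    sel_s: np.ndarray,
    sel_allele: np.ndarray,
) -> np.ndarray:
    """Draw gametes until one survives viability selection at all loci."""
    eval_pos = np.concatenate([positions_cM, sel_pos])
    while True:
        alleles = _sample_gamete_alleles(rng, length_cM, eval_pos)
        at_sel = alleles[len(positions_cM):]
        bad = at_sel != sel_allele
        if not bad.any():
            return alleles[: len(positions_cM)]
        if not (rng.random(bad.sum()) < sel_s[bad]).any():
            return alleles[: len(positions_cM)]


def simulate_meioses(config: SimConfig) -> TruthSet:
    """Simulate the F2 population and return true genotypes and positions.

    Each F2 individual is the union of two independent gametes of the F1.
    Crossovers per chromosome are Poisson(length in Morgans) with uniform
    positions (no interference).  Under gamete-viability distortion, a
    gamete carrying the non-selected allele at a distortion locus is
    rejected with probability s and redrawn; under zygote selection the
    whole individual survives with probability (1-s)^k where k is its
    number of non-selected allele copies over the distortion loci.
    """
    rng = np.random.default_rng(config.seed)
    marker_rows = []
    chrom_positions: list[np.ndarray] = []
    for c in range(config.n_chromosomes):
        m = config.markers_per_chrom[c]
        if config.marker_positions is not None:
            pos = np.sort(np.asarray(config.marker_positions[c], dtype=float))
            if len(pos) != m:
                raise ValueError("marker_positions length mismatch on chromosome %d" % (c + 1))
        else:
            pos = np.sort(rng.uniform(0.0, config.chrom_lengths_cM[c], size=m))
        chrom_positions.append(pos)
        poly = rng.random(m) < config.polymorphic_fraction
        for k in range(m):
            marker_rows.append(
                {
                    "marker_id": f"chr{c + 1:02d}_m{k + 1:04d}",
                    "chrom": c + 1,
                    "cM": pos[k],
                    "polymorphic": bool(poly[k]),
                }
            )
    positions = pd.DataFrame(marker_rows)

    sel_by_chrom: dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for d in config.distortion_loci:
        if not (1 <= d.chromosome <= config.n_chromosomes):
            raise ValueError(f"distortion locus on unknown chromosome {d.chromosome}")
        p, s, a = sel_by_chrom.setdefault(
            d.chromosome, (np.empty(0), np.empty(0), np.empty(0, dtype=np.int8))
        )
        sel_by_chrom[d.chromosome] = (
            np.append(p, d.position_cM),
            np.append(s, d.s),
            np.append(a, 0 if d.selected_allele == "a" else 1).astype(np.int8),
        )

    n = config.n_individuals
    geno_blocks = []
    zygote_mode = config.distortion_mechanism == "zygote"
    for c in range(config.n_chromosomes):
        pos = chrom_positions[c]
        length = config.chrom_lengths_cM[c]
        sel_pos, sel_s, sel_allele = sel_by_chrom.get(
            c + 1, (np.empty(0), np.empty(0), np.empty(0, dtype=np.int8))
        )
        block = np.empty((len(pos), n), dtype=np.int8)
        for i in range(n):
            while True:
                if len(sel_pos) and not zygote_mode:
                    g1 = _viable_gamete(rng, length, pos, sel_pos, sel_s, sel_allele)
                    g2 = _viable_gamete(rng, length, pos, sel_pos, sel_s, sel_allele)
                    block[:, i] = g1 + g2
                    break
                eval_pos = np.concatenate([pos, sel_pos])
                g1 = _sample_gamete_alleles(rng, length, eval_pos)
                g2 = _sample_gamete_alleles(rng, length, eval_pos)
                if zygote_mode and len(sel_pos):
                    # per-copy survival: multiply over offending allele copies
                    surv = 1.0
                    for j in range(len(sel_pos)):
                        k = int(g1[len(pos) + j] != sel_allele[j]) + int(
                            g2[len(pos) + j] != sel_allele[j]
                        )
                        surv *= (1.0 - sel_s[j]) ** k
                    if rng.random() >= surv:
                        continue
                block[:, i] = g1[: len(pos)] + g2[: len(pos)]
                break
        geno_blocks.append(block)

    genotypes = pd.DataFrame(
        np.vstack(geno_blocks),
        index=positions["marker_id"].to_numpy(),
        columns=[f"F2_{i + 1:03d}" for i in range(n)],
        dtype=np.int8,
    )
    return TruthSet(
        positions=positions,
        genotypes=genotypes,
        distortion_loci=config.distortion_loci,
        config=config,
    )


def _mutate_tag(rng: np.random.Generator, tag: str, config: SimConfig) -> tuple[str, str]:
    """Derive the second parental allele from the first: 1-3 SNPs, maybe an indel."""
    seq = list(tag)
    n_snp = int(rng.integers(1, 4))
    sites = rng.choice(len(seq), size=n_snp, replace=False)
    p_ts = config.ts_tv_ratio / (config.ts_tv_ratio + 1.0)
    for site in sites:
        base = seq[site]
        if rng.random() < p_ts:
            seq[site] = _TRANSITION[base]
        else:
            seq[site] = _TRANSVERSIONS[base][rng.integers(0, 2)]
    out = "".join(seq)
    if rng.random() < config.indel_fraction:
        cut = int(rng.integers(1, len(out) - 2))
        dlen = int(rng.integers(1, 3))
        out = out[:cut] + out[cut + dlen:]
        if rng.random() < 0.5:  # InDel_only: revert the substitutions
            base = list(tag)
            out = "".join(base[:cut] + base[cut + dlen:])
    return tag, out


def simulate_reads(truth: TruthSet, config: SimConfig | None = None) -> SimulatedReads:
    """Generate allele read counts for parents and offspring.

    Per marker x sample the total depth is Poisson(depth_mean) (negative
    binomial if ``depth_dispersion`` > 0); each read reports the true allele
    with probability 1 - seq_error_rate.  Heterozygotes draw each allele
    with probability 1/2 before error.  Zero depth yields no counts; called
    entries are additionally masked with probability ``missing_extra_rate``
    (applied to offspring only).
    """
    config = config or truth.config
    rng = np.random.default_rng(config.seed + 1)
    m = len(truth.positions)
    n = config.n_individuals
    eps = config.seq_error_rate

    # probability that a read reports allele A given true genotype
    p_a = np.array([1.0 - eps, 0.5, eps])

    def draw_depth(mean: float, shape: tuple) -> np.ndarray:
        if mean <= 0:
            return np.zeros(shape, dtype=np.int64)
        if config.depth_dispersion > 0:
            size = 1.0 / config.depth_dispersion
            lam = rng.gamma(size, mean / size, size=shape)
            return rng.poisson(lam)
        return rng.poisson(mean, size=shape)

    geno = truth.genotypes.to_numpy()
    poly = truth.positions["polymorphic"].to_numpy()

    depth_off = draw_depth(config.offspring_depth_mean, (m, n))
    mask = rng.random((m, n)) < config.missing_extra_rate
    depth_off[mask] = 0
    # non-polymorphic loci: all reads are allele A by construction
    pa_off = np.where(poly[:, None], p_a[geno], 1.0 - eps)
    ca_off = rng.binomial(depth_off, pa_off)
    cb_off = depth_off - ca_off

    dep_p1 = draw_depth(config.parent_depth_mean[0], (m,))
    dep_p2 = draw_depth(config.parent_depth_mean[1], (m,))
    # maternal parent is aa everywhere; paternal is bb at polymorphic loci
    ca_p1 = rng.binomial(dep_p1, 1.0 - eps)
    pa_p2 = np.where(poly, eps, 1.0 - eps)
    ca_p2 = rng.binomial(dep_p2, pa_p2)

    samples = ["P1", "P2"] + list(truth.genotypes.columns)
    count_a = pd.DataFrame(
        np.column_stack([ca_p1, ca_p2, ca_off]),
        index=truth.genotypes.index, columns=samples, dtype=np.int64,
    )
    count_b = pd.DataFrame(
        np.column_stack([dep_p1 - ca_p1, dep_p2 - ca_p2, cb_off]),
        index=truth.genotypes.index, columns=samples, dtype=np.int64,
    )

    tag_rows = []
    for mid, is_poly in zip(truth.positions["marker_id"], poly):
        tag = "".join(rng.choice(_BASES, size=config.tag_length))
        if is_poly:
            allele_a, allele_b = _mutate_tag(rng, tag, config)
        else:
            allele_a = allele_b = tag
        tag_rows.append({"marker_id": mid, "allele_a": allele_a, "allele_b": allele_b})
    loci = truth.positions.merge(pd.DataFrame(tag_rows), on="marker_id")

    return SimulatedReads(count_a=count_a, count_b=count_b, loci=loci)


def simulate_dataset(config: SimConfig) -> tuple[TruthSet, SimulatedReads]:
    """Convenience wrapper: meioses then reads under one config."""
    truth = simulate_meioses(config)
    return truth, simulate_reads(truth, config)


def write_truth(truth: TruthSet, out_dir) -> None:
    """Write the true map and genotype matrix as tab-delimited text."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth.positions.to_csv(out / "true_map.tsv", sep="\t", index=False)
    truth.genotypes.replace(GENO_LABELS).to_csv(out / "true_genotypes.tsv", sep="\t")


def write_counts(reads: SimulatedReads, out_dir) -> None:
    """Write the allele-count matrix in long form (marker, sample, countA, countB)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long = (
        reads.count_a.stack().rename("countA").to_frame()
        .join(reads.count_b.stack().rename("countB"))
        .reset_index()
    )
    long.columns = ["marker_id", "individual_id", "countA", "countB"]
    long.to_csv(out / "allele_counts.tsv", sep="\t", index=False)
    reads.loci.to_csv(out / "loci.tsv", sep="\t", index=False)
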