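"""SLAF locus identification and marker classification.

A SLAF locus is a group of near-identical restriction-fragment tags.  This
module clusters equal-length tags by Hamming identity (single linkage at
95%, a deliberate simplification of alignment-based clustering that is
exact for fixed-length tags), defines the two alleles of a locus by
minor-allele-frequency evaluation, applies the locus-level filters
(repetitive, SNP excess, low depth), assigns one of the eight biparental
segregation patterns, and types the parental variant (SNP IUPAC classes
and/or InDel).

Only the aa x bb pattern — both parents homozygous for different alleles —
is fully informative in an F2 from homozygous parents and is carried
forward to map construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from Bio import Align

__all__ = [
    "SlafLocus", "MarkerRecord", "cluster_tags", "define_alleles",
    "classify_locus", "classify_segregation_pattern", "classify_variant",
    "SEGREGATION_PATTERNS", "IUPAC_SNP_TYPES",
]

SEGREGATION_PATTERNS = ("ab×cd", "ef×eg", "hk×hk", "lm×ll", "nn×np",
                        "aa×bb", "ab×cc", "cc×ab")

#: IUPAC ambiguity code of each unordered base pair
IUPAC_SNP_TYPES = {
    frozenset("GA"): "R",
    frozenset("TC"): "Y",
    frozenset("GC"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}

LOW_DEPTH_DEFAULT = 2.20


@dataclass
class SlafLocus:
    """One clustered SLAF tag group with per-tag read counts."""

    locus_id: str
    tags: list  # (sequence, sample, read_count) triples
    status: str = "unclassified"
    n_snps_between_parents: int | None = None

    @property
    def n_distinct_tags(self) -> int:
        return len({seq for seq, _, _ in self.tags})

    def tag_counts(self) -> dict[str, int]:
        counts: Counter = Counter()
        for seq, _, c in self.tags:
            counts[seq] += c
        return dict(counts)


@dataclass
class MarkerRecord:
    """A polymorphic marker with its pattern and variant classification."""

    marker_id: str
    segregation_pattern: str
    variant_class: str  # SNP_only / InDel_only / SNP&InDel
    snp_types: tuple
    parent_alleles: tuple  # (maternal genotype, paternal genotype)
    status: str = "candidate"  # candidate / framework / accessory / filtered


class UnequalTagLengthError(ValueError):
    """Tags of differing length cannot be compared by positional identity."""


def _identity(a: str, b: str) -> float:
    matches = sum(x == y for x, y in zip(a, b))
    return matches / len(a)


def cluster_tags(tag_sequences: list[str], identity_threshold: float = 0.95
                 ) -> list[list[int]]:
    """Single-linkage clustering of equal-length tags into loci.

    Two tags link iff their fraction of matching positions exceeds
    ``identity_threshold``; clusters are the transitive closure of links,
    so the partition is independent of input order.  Returns lists of tag
    indices, each list one locus, sorted by smallest member.

    Raises
    ------
    UnequalTagLengthError
        If tag lengths differ (positional identity is then undefined).
    """
    if not tag_sequences:
        return []
    length = len(tag_sequences[0])
    for t in tag_sequences:
        if len(t) != length:
            raise UnequalTagLengthError(
                f"tag length {len(t)} != {length}; equal-length tags required"
            )
    n = len(tag_sequences)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if _identity(tag_sequences[i], tag_sequences[j]) > identity_threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    return [sorted(v) for _, v in sorted(clusters.items())]


def define_alleles(tag_counts: dict[str, int]) -> tuple[tuple[str, str], float] | None:
    """Pick the locus alleles by minor-allele-frequency evaluation.

    The two highest-count tags become alleles A and B (ties broken
    lexicographically by sequence for determinism); the reported MAF is
    minor count / total count over all tags.  Returns ``None`` for a
    monomorphic locus (a single tag).
    """
    if len(tag_counts) < 2:
        return None
    ranked = sorted(tag_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (a_seq, a_n), (b_seq, b_n) = ranked[0], ranked[1]
    total = sum(tag_counts.values())
    maf = min(a_n, b_n) / total
    return (a_seq, b_seq), maf


def classify_locus(locus: SlafLocus, parents_differ: bool,
                   mean_depth: float,
                   low_depth_threshold: float = LOW_DEPTH_DEFAULT,
                   max_parent_snps: int = 3) -> str:
    """Assign the locus filter status.

    Order of precedence: repetitive (> 4 distinct tags), SNP excess
    (> ``max_parent_snps`` SNPs between the parental alleles), low depth
    (mean sequence depth below ``low_depth_threshold``), then polymorphic
    (2-4 tags with differing parents) or non-polymorphic.
    """
    if locus.n_distinct_tags > 4:
        locus.status = "repetitive"
    elif (locus.n_snps_between_parents or 0) > max_parent_snps:
        locus.status = "filtered_snp_excess"
    elif mean_depth < low_depth_threshold:
        locus.status = "low_depth"
    elif parents_differ and 2 <= locus.n_distinct_tags <= 4:
        locus.status = "polymorphic"
    else:
        locus.status = "non_polymorphic"
    return locus.status


def classify_segregation_pattern(maternal: tuple[str, str] | None,
                                 paternal: tuple[str, str] | None) -> str:
    """Map the two parental genotypes to one of the eight patterns.

    Genotypes are unordered allele pairs; ``None`` (uncallable parent)
    yields 'undetermined', as do two identical homozygotes.  Only aa×bb is
    usable for this F2 design; the heterozygous-parent patterns arise from
    residual parental heterozygosity and are dropped upstream.
    """
    if maternal is None or paternal is None:
        return "undetermined"
    ma, pa = frozenset(maternal), frozenset(paternal)
    m_het, p_het = len(ma) == 2, len(pa) == 2
    if m_het and p_het:
        shared = ma & pa
        if ma == pa:
            return "hk×hk"
        if shared:
            return "ef×eg"
        return "ab×cd"
    if m_het and not p_het:
        return "lm×ll" if pa <= ma else "ab×cc"
    if p_het and not m_het:
        return "nn×np" if ma <= pa else "cc×ab"
    return "aa×bb" if ma != pa else "undetermined"


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -3
_aligner.extend_gap_score = -0.5


def classify_variant(allele_a: str, allele_b: str) -> tuple[str, tuple]:
    """Type the parental variant: SNP IUPAC classes and/or InDel.

    Equal-length alleles are compared positionally; length-changing alleles
    are globally aligned first and gap columns count as one InDel each
    (a gap run is one event).  Substitution columns are typed by the IUPAC
    ambiguity code of the unordered base pair.

    Returns ``(variant_class, snp_types)`` with variant_class one of
    'SNP_only', 'InDel_only', 'SNP&InDel' ('identical' if no difference).
    """
    for s in (allele_a, allele_b):
        if set(s) - set("ACGT"):
            raise ValueError(f"non-ACGT characters in allele sequence: {s!r}")
    if len(allele_a) == len(allele_b):
        aligned_a, aligned_b = allele_a, allele_b
    else:
        aln = _aligner.align(allele_a, allele_b)[0]
        aligned_a, aligned_b = str(aln[0]), str(aln[1])

    snp_types: list[str] = []
    n_indel = 0
    in_gap = False
    for x, y in zip(aligned_a, aligned_b):
        if x == "-" or y == "-":
            if not in_gap:
                n_indel += 1
            in_gap = True
            continue
        in_gap = False
        if x != y:
            snp_types.append(IUPAC_SNP_TYPES[frozenset((x, y))])
    if snp_types and n_indel:
        cls = "SNP&InDel"
    elif snp_types:
        cls = "SNP_only"
    elif n_indel:
        cls = "InDel_only"
    else:
        cls = "identical"
    return cls, tuple(snp_types)


def count_parent_snps(allele_a: str, allele_b: str) -> int:
    """Number of SNPs between the two parental alleles (for the excess filter)."""
    _, types = classify_variant(allele_a, allele_b)
    return len(types)
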