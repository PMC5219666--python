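"""SLAF locus clustering, allele definition and marker classification."""

import numpy as np
import pytest

from slafmap.slaf_markers import (SlafLocus, UnequalTagLengthError,
                                  classify_locus, classify_segregation_pattern,
                                  classify_variant, cluster_tags, define_alleles,
                                  count_parent_snps)


def mutate(seq, positions, base="T"):
    s = list(seq)
    for p in positions:
        s[p] = base if s[p] != base else "G"
    return "".join(s)


BASE = ("ACGT" * 25)  # 100-mer


class TestClusterTags:
    def test_identical_tags_one_locus(self):
        assert cluster_tags([BASE, BASE]) == [[0, 1]]

    def test_six_differences_split(self):
        # 94% identity is below the 95% threshold
        other = mutate(BASE, range(6))
        assert cluster_tags([BASE, other]) == [[0], [1]]

    def test_single_linkage_closure(self):
        # A~B and B~C above threshold, A~C below: one locus of all three
        a = BASE
        b = mutate(BASE, range(4))          # 96% to a
        c = mutate(b, range(90, 94))        # 96% to b, 92% to a
        assert cluster_tags([a, b, c]) == [[0, 1, 2]]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(UnequalTagLengthError):
            cluster_tags([BASE, BASE[:-1]])

    def test_order_independent(self):
        a, b = BASE, mutate(BASE, range(6))
        c = mutate(BASE, range(50, 53))
        p1 = cluster_tags([a, b, c])
        p2 = cluster_tags([c, a, b])
        assert len(p1) == len(p2) == 2


class TestDefineAlleles:
    def test_maf_from_top_two(self):
        (a, b), maf = define_alleles({"T1": 90, "T2": 60})
        assert (a, b) == ("T1", "T2")
        assert maf == pytest.approx(60 / 150)

    def test_single_tag_monomorphic(self):
        assert define_alleles({"T1": 100}) is None

    def test_top_two_rule_with_minor_third(self):
        (a, b), _ = define_alleles({"T1": 50, "T2": 50, "T3": 2})
        assert {a, b} == {"T1", "T2"}
        assert a < b  # lexicographic tie-break


class TestClassifyLocus:
    def test_repetitive_above_four_tags(self):
        tags = [(mutate(BASE, [i]), f"s{i}", 5) for i in range(5)]
        locus = SlafLocus("L1", tags)
        assert classify_locus(locus, True, 10.0) == "repetitive"

    def test_snp_excess_filtered(self):
        locus = SlafLocus("L2", [(BASE, "p1", 5), (mutate(BASE, range(4)), "p2", 5)])
        locus.n_snps_between_parents = count_parent_snps(BASE, mutate(BASE, range(4)))
        assert locus.n_snps_between_parents == 4
        assert classify_locus(locus, True, 10.0) == "filtered_snp_excess"

    def test_identical_parents_non_polymorphic(self):
        locus = SlafLocus("L3", [(BASE, "p1", 5), (BASE, "p2", 5)])
        assert classify_locus(locus, False, 10.0) == "non_polymorphic"

    def test_low_depth(self):
        locus = SlafLocus("L4", [(BASE, "p1", 1), (mutate(BASE, [0]), "p2", 1)])
        locus.n_snps_between_parents = 1
        assert classify_locus(locus, True, 2.0) == "low_depth"

    def test_polymorphic(self):
        locus = SlafLocus("L5", [(BASE, "p1", 5), (mutate(BASE, [0]), "p2", 5)])
        locus.n_snps_between_parents = 1
        assert classify_locus(locus, True, 10.0) == "polymorphic"


class TestSegregationPatterns:
    @pytest.mark.parametrize("mat,pat,expected", [
        (("a", "a"), ("b", "b"), "aa×bb"),
        (("a", "b"), ("c", "c"), "ab×cc"),
        (("c", "c"), ("a", "b"), "cc×ab"),
        (("a", "b"), ("c", "d"), "ab×cd"),
        (("e", "f"), ("e", "g"), "ef×eg"),
        (("h", "k"), ("h", "k"), "hk×hk"),
        (("l", "m"), ("l", "l"), "lm×ll"),
        (("n", "n"), ("n", "p"), "nn×np"),
        (("a", "a"), ("a", "a"), "undetermined"),
        (None, ("a", "a"), "undetermined"),
    ])
    def test_all_parental_combinations(self, mat, pat, expected):
        assert classify_segregation_pattern(mat, pat) == expected

    def test_classification_is_total_and_single_valued(self):
        alleles = "abcd"
        seen = set()
        for m1 in alleles:
            for m2 in alleles:
                for p1 in alleles:
                    for p2 in alleles:
                        out = classify_segregation_pattern((m1, m2), (p1, p2))
                        assert isinstance(out, str)
                        seen.add(out)
        assert seen <= {"ab×cd", "ef×eg", "hk×hk", "lm×ll", "nn×np",
                        "aa×bb", "ab×cc", "cc×ab", "undetermined"}


class TestVariantClassification:
    def test_single_transition_is_R(self):
        a = BASE
        b = a[:10] + "A" + a[11:]  # G -> A at position 10
        assert a[10] == "G"
        cls, types = classify_variant(a, b)
        assert cls == "SNP_only" and types == ("R",)

    def test_two_base_deletion_is_indel_only(self):
        a = BASE
        b = a[:40] + a[42:]
        cls, types = classify_variant(a, b)
        assert cls == "InDel_only" and types == ()

    def test_substitution_plus_deletion(self):
        a = BASE
        b = a[:3] + "C" + a[4:40] + a[42:]  # T->C at 3, deletion at 40
        assert a[3] == "T"
        cls, types = classify_variant(a, b)
        assert cls == "SNP&InDel" and types == ("Y",)

    def test_non_acgt_rejected(self):
        with pytest.raises(ValueError):
            classify_variant("ACGN", "ACGT")

    @pytest.mark.parametrize("pair,code", [
        (("G", "A"), "R"), (("T", "C"), "Y"), (("G", "C"), "S"),
        (("A", "T"), "W"), (("G", "T"), "K"), (("A", "C"), "M"),
    ])
    def test_iupac_codes_partition_all_substitutions(self, pair, code):
        a = "A" * 20 + pair[0] + "A" * 20
        b = "A" * 20 + pair[1] + "A" * 20
        _, types = classify_variant(a, b)
        assert types == (code,)

    def test_transition_fraction_recovers_ts_tv_ratio(self):
        # simulated tags with ts:tv = 2 should give ~2/3 transitions
        from slafmap.simdata import SimConfig, simulate_dataset
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(50.0,),
                        markers_per_chrom=(600,), n_individuals=2,
                        polymorphic_fraction=1.0, ts_tv_ratio=2.0,
                        indel_fraction=0.0, seed=8)
        _, reads = simulate_dataset(cfg)
        counts = {"R": 0, "Y": 0, "S": 0, "W": 0, "K": 0, "M": 0}
        for _, row in reads.loci.iterrows():
            _, types = classify_variant(row["allele_a"], row["allele_b"])
            for t in types:
                counts[t] += 1
        total = sum(counts.values())
        ts_frac = (counts["R"] + counts["Y"]) / total
        assert abs(ts_frac - 2 / 3) < 0.05
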