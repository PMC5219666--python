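"""Simulator: meiosis model, viability selection, read generation."""

import numpy as np
import pytest

from slafmap.linkage import pairwise_r_lod
from slafmap.simdata import (DistortionLocus, SimConfig, simulate_dataset,
                             simulate_meioses, simulate_reads)


def haldane(d_cM):
    return (1.0 - np.exp(-2.0 * d_cM / 100.0)) / 2.0


class TestConfigValidation:
    def test_selection_coefficient_bounds(self):
        with pytest.raises(ValueError):
            DistortionLocus(1, 10.0, 1.5, "a")

    def test_bad_allele(self):
        with pytest.raises(ValueError):
            DistortionLocus(1, 10.0, 0.5, "x")

    def test_nonfinite_length_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(n_chromosomes=1, chrom_lengths_cM=(float("nan"),),
                      markers_per_chrom=(5,))

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(seq_error_rate=1.5)

    def test_scalar_parent_depth_broadcast(self):
        cfg = SimConfig(parent_depth_mean=20.0)
        assert cfg.parent_depth_mean == (20.0, 20.0)


class TestMeiosis:
    def test_zero_length_chromosome_cosegregates(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(0.0,),
                        markers_per_chrom=(2,), n_individuals=80,
                        polymorphic_fraction=1.0, seed=1)
        t = simulate_meioses(cfg)
        g = t.genotypes.to_numpy()
        assert (g[0] == g[1]).all()

    def test_recombinant_fraction_matches_haldane(self):
        # two markers 20 cM apart; no interference => r = (1 - e^-0.4)/2
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(20.0,),
                        markers_per_chrom=(2,), n_individuals=10_000,
                        marker_positions=((0.0, 20.0),),
                        polymorphic_fraction=1.0, seed=2)
        t = simulate_meioses(cfg)
        r_hat, _, _ = pairwise_r_lod(t.genotypes.to_numpy())
        r_exp = haldane(20.0)
        se = np.sqrt(r_exp * (1 - r_exp) / (2 * 10_000))
        assert abs(r_hat[0, 1] - r_exp) < 3 * se

    def test_complete_selection_removes_homozygote(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(50.0,),
                        markers_per_chrom=(3,), n_individuals=400,
                        marker_positions=((0.0, 25.0, 50.0),),
                        polymorphic_fraction=1.0, seed=3,
                        distortion_loci=(DistortionLocus(1, 25.0, 1.0, "a"),))
        t = simulate_meioses(cfg)
        assert (t.genotypes.to_numpy()[1] != 2).all()  # no bb at the locus

    def test_zygote_selection_mode_runs(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(50.0,),
                        markers_per_chrom=(3,), n_individuals=200,
                        polymorphic_fraction=1.0, seed=3,
                        distortion_mechanism="zygote",
                        distortion_loci=(DistortionLocus(1, 25.0, 0.9, "a"),))
        t = simulate_meioses(cfg)
        mid = 1
        counts = np.bincount(t.genotypes.to_numpy()[mid], minlength=3)
        assert counts[0] > counts[2]  # selected homozygote enriched

    def test_monotone_recombination_with_distance(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(120.0,),
                        markers_per_chrom=(5,), n_individuals=4000,
                        marker_positions=((0.0, 10.0, 30.0, 70.0, 120.0),),
                        polymorphic_fraction=1.0, seed=4)
        t = simulate_meioses(cfg)
        r_hat, _, _ = pairwise_r_lod(t.genotypes.to_numpy())
        rs = [r_hat[0, j] for j in range(1, 5)]
        assert all(b >= a - 0.02 for a, b in zip(rs, rs[1:]))

    def test_mendelian_ratio_at_unselected_locus(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(50.0,),
                        markers_per_chrom=(2,), n_individuals=8000,
                        polymorphic_fraction=1.0, seed=6)
        t = simulate_meioses(cfg)
        freq = np.bincount(t.genotypes.to_numpy()[0], minlength=3) / 8000
        assert np.allclose(freq, [0.25, 0.5, 0.25], atol=0.02)


class TestReads:
    def test_zero_depth_means_no_counts(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(10.0,),
                        markers_per_chrom=(3,), n_individuals=30,
                        offspring_depth_mean=0.0, polymorphic_fraction=1.0, seed=1)
        truth, reads = simulate_dataset(cfg)
        prog = [c for c in reads.count_a.columns if not c.startswith("P")]
        assert (reads.count_a[prog].to_numpy() == 0).all()
        assert (reads.count_b[prog].to_numpy() == 0).all()

    def test_homozygote_reads_one_allele_without_error(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(10.0,),
                        markers_per_chrom=(4,), n_individuals=60,
                        offspring_depth_mean=10.0, seq_error_rate=1e-12,
                        missing_extra_rate=0.0, polymorphic_fraction=1.0, seed=2)
        truth, reads = simulate_dataset(cfg)
        prog = [c for c in reads.count_a.columns if not c.startswith("P")]
        g = truth.genotypes.to_numpy()
        cb = reads.count_b[prog].to_numpy()
        ca = reads.count_a[prog].to_numpy()
        assert (cb[g == 0] == 0).all()
        assert (ca[g == 2] == 0).all()

    def test_heterozygote_allele_balance(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(10.0,),
                        markers_per_chrom=(2,), n_individuals=4000,
                        offspring_depth_mean=6.0, seq_error_rate=1e-12,
                        missing_extra_rate=0.0, polymorphic_fraction=1.0, seed=3)
        truth, reads = simulate_dataset(cfg)
        prog = [c for c in reads.count_a.columns if not c.startswith("P")]
        g = truth.genotypes.to_numpy()
        ca = reads.count_a[prog].to_numpy()[g == 1]
        cb = reads.count_b[prog].to_numpy()[g == 1]
        total = (ca + cb).sum()
        frac = ca.sum() / total
        se = np.sqrt(0.25 / total)
        assert abs(frac - 0.5) < 3 * se

    def test_fixed_seed_reproducible(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(30.0,),
                        markers_per_chrom=(5,), n_individuals=40, seed=9)
        t1, r1 = simulate_dataset(cfg)
        t2, r2 = simulate_dataset(SimConfig(
            n_chromosomes=1, chrom_lengths_cM=(30.0,), markers_per_chrom=(5,),
            n_individuals=40, seed=9))
        assert t1.genotypes.equals(t2.genotypes)
        assert r1.count_a.equals(r2.count_a)
        assert list(r1.loci["allele_a"]) == list(r2.loci["allele_a"])

    def test_nonpolymorphic_loci_have_identical_alleles(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(30.0,),
                        markers_per_chrom=(40,), n_individuals=10,
                        polymorphic_fraction=0.3, seed=10)
        truth, reads = simulate_dataset(cfg)
        poly = reads.loci["polymorphic"].to_numpy()
        same = (reads.loci["allele_a"] == reads.loci["allele_b"]).to_numpy()
        assert (same[~poly]).all()
        assert not same[poly].any()
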