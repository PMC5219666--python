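"""Two-point EM estimation, LOD scores and linkage grouping."""

import numpy as np
import pytest

from slafmap.linkage import (correlation_lod, estimate_r_em, group_markers,
                             group_markers_robust, joint_class_probs,
                             lod_score, pairwise_r_lod, pairwise_r_lod_counts)


def grid_search_r(table, step=1e-4):
    grid = np.arange(step, 0.5 + step / 2, step)
    lls = [np.sum(table * np.log10(np.maximum(joint_class_probs(r), 1e-300)))
           for r in grid]
    return grid[int(np.argmax(lls))]


class TestEstimateR:
    def test_perfect_cosegregation_clamps_to_zero(self):
        table = np.diag([32, 65, 33])
        res = estimate_r_em(table)
        assert res.r_hat == pytest.approx(0.0, abs=1e-6)

    def test_expected_table_returns_generating_r(self):
        table = joint_class_probs(0.2) * 10_000
        res = estimate_r_em(table)
        assert res.r_hat == pytest.approx(0.2, abs=1e-6)

    def test_independent_margins_give_half(self):
        table = np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25]) * 500
        res = estimate_r_em(table)
        assert res.r_hat == pytest.approx(0.5, abs=1e-6)
        assert res.lod == pytest.approx(0.0, abs=1e-9)

    def test_em_matches_grid_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            r_true = rng.uniform(0.02, 0.45)
            table = rng.multinomial(130, joint_class_probs(r_true).ravel()).reshape(3, 3)
            res = estimate_r_em(table)
            if res.phase == "coupling":
                assert abs(res.r_hat - grid_search_r(table)) <= 1e-4

    def test_allele_swap_invariance(self):
        rng = np.random.default_rng(8)
        table = rng.multinomial(130, joint_class_probs(0.15).ravel()).reshape(3, 3)
        res = estimate_r_em(table)
        res_swapped = estimate_r_em(table[:, ::-1])  # relabel marker-2 alleles
        res_transposed = estimate_r_em(table.T)      # swap marker labels
        assert res_swapped.r_hat == pytest.approx(res.r_hat, abs=1e-7)
        assert res_transposed.r_hat == pytest.approx(res.r_hat, abs=1e-7)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            estimate_r_em(np.zeros((3, 3)))


class TestLod:
    def test_lod_zero_at_half(self):
        table = np.outer([25, 50, 25], [25, 50, 25]) / 100.0
        assert lod_score(table, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_fully_linked_lod_matches_direct_evaluation(self):
        table = np.diag([32.5, 65.0, 32.5])  # n = 130, r -> 0
        r = 1e-7
        direct = (np.sum(table * np.log10(joint_class_probs(r)))
                  - np.sum(table * np.log10(joint_class_probs(0.5))))
        assert lod_score(table, r) == pytest.approx(direct)
        # homozygote cells gain log10(4), het cells log10(2)
        assert lod_score(table, r) == pytest.approx(
            65.0 * np.log10(4) + 65.0 * np.log10(2), abs=1e-3)

    def test_lod_nonnegative_at_mle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            table = rng.multinomial(130, np.full(9, 1 / 9)).reshape(3, 3)
            res = estimate_r_em(table)
            assert res.lod >= 0.0


class TestPairwise:
    def test_matches_single_pair_estimates(self, small_truth):
        codes = small_truth.genotypes.to_numpy()[:8]
        from slafmap.linkage import _joint_count_tables
        r_mat, lod_mat, n_mat = pairwise_r_lod(codes)
        tables = _joint_count_tables(codes)
        for i in range(8):
            for j in range(i + 1, 8):
                res = estimate_r_em(tables[i, j])
                assert r_mat[i, j] == pytest.approx(res.r_hat, abs=1e-6)
                assert lod_mat[i, j] == pytest.approx(res.lod, abs=1e-6)
                assert n_mat[i, j] == res.n_informative

    def test_count_based_matches_truth_at_high_depth(self, small_truth):
        # deep reads pin the genotypes, so the read-count EM must agree
        # with the hard-genotype EM
        from slafmap.simdata import SimConfig, simulate_dataset
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(80.0,),
                        markers_per_chrom=(8,), n_individuals=300,
                        offspring_depth_mean=25.0, missing_extra_rate=0.0,
                        polymorphic_fraction=1.0, seed=12)
        truth, reads = simulate_dataset(cfg)
        prog = [c for c in reads.count_a.columns if not c.startswith("P")]
        r_gl, _, _ = pairwise_r_lod_counts(reads.count_a[prog].to_numpy(),
                                           reads.count_b[prog].to_numpy())
        r_hard, _, _ = pairwise_r_lod(truth.genotypes.to_numpy())
        near = r_hard < 0.35  # distant pairs carry almost no information
        assert np.abs(r_gl - r_hard)[near].max() < 0.04


class TestGrouping:
    def _block_lod(self):
        lod = np.zeros((10, 10))
        for block in (range(5), range(5, 10)):
            for i in block:
                for j in block:
                    if i != j:
                        lod[i, j] = 10.0
        return lod

    def test_two_clusters(self):
        res = group_markers(self._block_lod(), 5.0)
        assert res.n_groups == 2
        assert res.groups[0] == [0, 1, 2, 3, 4]

    def test_threshold_above_maximum_unlinks_everything(self):
        res = group_markers(self._block_lod(), 50.0)
        assert res.n_groups == 0
        assert len(res.unlinked) == 10

    def test_ten_chromosome_recovery_on_clean_genotypes(self):
        from slafmap.simdata import SimConfig, simulate_meioses
        cfg = SimConfig(n_chromosomes=10, chrom_lengths_cM=(140.0,) * 10,
                        markers_per_chrom=(20,) * 10, n_individuals=130,
                        marker_positions=tuple(np.linspace(0, 140, 20)
                                               for _ in range(10)),
                        polymorphic_fraction=1.0, seed=13)
        truth = simulate_meioses(cfg)
        _, lod, _ = pairwise_r_lod(truth.genotypes.to_numpy())
        res = group_markers(lod, 5.0)
        assert res.n_groups == 10
        chrom = truth.positions["chrom"].to_numpy()
        for grp in res.groups:
            assert len(set(chrom[grp])) == 1

    def test_robust_grouping_ignores_single_chance_edge(self):
        lod = self._block_lod()
        lod[0, 7] = lod[7, 0] = 6.0  # one spurious bridge
        plain = group_markers(lod, 5.0)
        robust = group_markers_robust(lod, 5.0)
        assert plain.n_groups == 1  # transitive closure welds the blocks
        assert robust.n_groups == 2

    def test_correlation_lod_immune_to_shared_distortion(self):
        # two unlinked markers, both heavily skewed: the model LOD sees
        # linkage, the dosage-correlation MLOD does not
        rng = np.random.default_rng(14)
        n = 130
        probs = [0.64, 0.32, 0.04]  # strong distortion toward aa
        a = rng.choice(3, size=n, p=probs)
        b = rng.choice(3, size=n, p=probs)
        codes = np.stack([a, b]).astype(np.int8)
        _, model_lod, _ = pairwise_r_lod(codes)
        _, adj_lod, _ = pairwise_r_lod(codes, margin_adjusted=True)
        corr = correlation_lod(codes)
        assert model_lod[0, 1] > 2.0
        assert adj_lod[0, 1] < model_lod[0, 1]  # margin baseline absorbs it
        assert corr[0, 1] < 2.0

    def test_empty_matrix(self):
        res = group_markers(np.zeros((0, 0)), 5.0)
        assert res.groups == [] and res.unlinked == []
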