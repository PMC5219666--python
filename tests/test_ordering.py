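"""SARF ordering, multipoint re-estimation, SMOOTH, imputation, Kosambi."""

import itertools

import numpy as np
import pytest

from slafmap.linkage import pairwise_r_lod
from slafmap.ordering import (LinkageGroup, insert_skewed, knn_impute, kosambi,
                              kosambi_inverse, multipoint_update, order_sa,
                              posterior_impute, sarf, smooth_correct)
from slafmap.simdata import SimConfig, simulate_meioses


def haldane_r_matrix(positions):
    d = np.abs(np.asarray(positions)[:, None] - np.asarray(positions)[None, :])
    return (1.0 - np.exp(-2.0 * d / 100.0)) / 2.0


class TestSarf:
    def test_single_marker_is_zero(self):
        assert sarf([0], np.zeros((1, 1))) == 0.0

    def test_direct_sum(self):
        r = np.zeros((3, 3))
        r[0, 1] = r[1, 0] = 0.1
        r[1, 2] = r[2, 1] = 0.2
        r[0, 2] = r[2, 0] = 0.4
        assert sarf([0, 1, 2], r) == pytest.approx(0.3)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(0)
        r = rng.uniform(0, 0.5, (6, 6))
        r = (r + r.T) / 2
        order = rng.permutation(6)
        assert sarf(order, r) == pytest.approx(sarf(order[::-1], r))

    def test_missing_pairwise_r_rejected(self):
        r = np.full((3, 3), np.nan)
        with pytest.raises(ValueError):
            sarf([0, 1, 2], r)


class TestKosambi:
    def test_zero(self):
        assert kosambi(0.0) == 0.0

    def test_quarter(self):
        assert kosambi(0.25) == pytest.approx(25.0 * np.log(3.0))
        assert kosambi(0.25) == pytest.approx(27.465, abs=1e-3)

    def test_round_trip_identity(self):
        for r in np.arange(0.01, 0.50, 0.01):
            assert abs(kosambi_inverse(kosambi(r)) - r) < 1e-12

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi(-0.01)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)

    def test_monotone(self):
        vals = [kosambi(r) for r in np.linspace(0, 0.49, 50)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestOrderSA:
    def test_eight_markers_reach_exhaustive_optimum(self, small_truth):
        rng = np.random.default_rng(1)
        for trial in range(3):
            sel = rng.choice(12, size=8, replace=False)
            codes = small_truth.genotypes.to_numpy()[sel]
            r, lod, _ = pairwise_r_lod(codes)
            perm = rng.permutation(8)
            r_p, lod_p = r[np.ix_(perm, perm)], lod[np.ix_(perm, perm)]
            state = order_sa(r_p, lod_p, seed=trial)
            best = min(sarf(list(o), r_p)
                       for o in itertools.permutations(range(8)))
            assert state.sarf == pytest.approx(best, abs=1e-12)

    def test_optimal_input_is_stable(self):
        pos = [0, 5, 12, 20, 30, 45]
        r = haldane_r_matrix(pos)
        state = order_sa(r, seed=3)
        assert state.sarf == pytest.approx(sarf(range(6), r), abs=1e-12)

    def test_incomplete_r_structure_rejected(self):
        r = np.full((4, 4), np.nan)
        with pytest.raises(ValueError):
            order_sa(r, seed=0)

    def test_fixed_seed_reproducible(self, small_truth):
        codes = small_truth.genotypes.to_numpy()[:12]
        r, lod, _ = pairwise_r_lod(codes)
        s1 = order_sa(r, lod, seed=7)
        s2 = order_sa(r, lod, seed=7)
        assert (s1.order == s2.order).all()

    def test_twenty_marker_recovery(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(120.0,),
                        markers_per_chrom=(20,), n_individuals=130,
                        marker_positions=(np.linspace(0, 120, 20),),
                        polymorphic_fraction=1.0, seed=17)
        truth = simulate_meioses(cfg)
        codes = truth.genotypes.to_numpy()
        rng = np.random.default_rng(2)
        perm = rng.permutation(20)
        r, lod, _ = pairwise_r_lod(codes[perm])
        state = order_sa(r, lod, seed=5)
        recovered = perm[state.order]
        if recovered[0] > recovered[-1]:
            recovered = recovered[::-1]
        from scipy.stats import kendalltau
        tau = kendalltau(recovered, range(20)).statistic
        assert abs(tau) >= 0.95

    def test_sarf_no_worse_than_true_order_on_clean_data(self, small_truth):
        # the optimum under the objective can only match or beat the truth
        codes = small_truth.genotypes.to_numpy()[:12]  # chromosome 1, in order
        r, lod, _ = pairwise_r_lod(codes)
        state = order_sa(r, lod, seed=11)
        assert state.sarf <= sarf(range(12), r) + 1e-9


class TestMultipoint:
    def test_complete_data_equals_two_point(self, small_truth):
        codes = small_truth.genotypes.to_numpy()[:12]
        r, _, _ = pairwise_r_lod(codes)
        adj = np.array([r[i, i + 1] for i in range(11)])
        updated = multipoint_update(codes, adj)
        assert np.allclose(updated, adj, atol=1e-6)

    def test_cycle_zero_returns_input(self, small_truth):
        codes = small_truth.genotypes.to_numpy()[:12]
        adj = np.full(11, 0.1)
        assert (multipoint_update(codes, adj, n_cycles=0) == adj).all()

    def test_missing_marginalization_beats_complete_case(self):
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(100.0,),
                        markers_per_chrom=(15,), n_individuals=200,
                        marker_positions=(np.linspace(0, 100, 15),),
                        polymorphic_fraction=1.0, seed=19)
        truth = simulate_meioses(cfg)
        codes = truth.genotypes.to_numpy().copy()
        pos = truth.positions["cM"].to_numpy()
        r_true = np.array([(1 - np.exp(-2 * (pos[i + 1] - pos[i]) / 100)) / 2
                           for i in range(14)])
        rng = np.random.default_rng(3)
        codes[rng.random(codes.shape) < 0.25] = -1
        r2, _, _ = pairwise_r_lod(codes)
        adj_complete = np.array([r2[i, i + 1] for i in range(14)])
        adj_multi = multipoint_update(codes, adj_complete, n_cycles=10)
        rmse_c = np.sqrt(np.mean((adj_complete - r_true) ** 2))
        rmse_m = np.sqrt(np.mean((adj_multi - r_true) ** 2))
        assert rmse_m <= rmse_c + 1e-6


class TestSmooth:
    def _clean_block(self, n_markers=15, n_ind=100, spacing=2.0, seed=23):
        cfg = SimConfig(n_chromosomes=1,
                        chrom_lengths_cM=(spacing * (n_markers - 1),),
                        markers_per_chrom=(n_markers,), n_individuals=n_ind,
                        marker_positions=(np.arange(n_markers) * spacing,),
                        polymorphic_fraction=1.0, seed=seed)
        truth = simulate_meioses(cfg)
        return truth.genotypes.to_numpy().copy(), truth.positions["cM"].to_numpy()

    def test_planted_flip_inside_block_removed(self):
        codes, pos = self._clean_block()
        # flip one genotype to the opposite homozygote inside a run
        target = None
        for i in range(3, 12):
            if codes[i - 1, 0] == codes[i, 0] == codes[i + 1, 0] == 0:
                target = i
                break
        assert target is not None
        codes[target, 0] = 2
        corrected, log = smooth_correct(codes, pos)
        assert corrected[target, 0] == -1
        assert any(e["marker_index"] == target and e["individual_index"] == 0
                   for e in log)

    def test_error_free_matrix_unchanged(self):
        # at 5 cM spacing a genuine single recombinant is well above the
        # default improbability threshold, so nothing may be touched
        codes, pos = self._clean_block(spacing=5.0, seed=24)
        corrected, log = smooth_correct(codes, pos)
        assert log == []
        assert (corrected == codes).all()

    def test_map_length_decreases_with_planted_errors(self):
        shrunk = 0
        for seed in range(3):
            codes, pos = self._clean_block(seed=30 + seed)
            rng = np.random.default_rng(seed)
            flips = rng.random(codes.shape) < 0.01
            noisy = codes.copy()
            noisy[flips] = (noisy[flips] + rng.integers(1, 3, flips.sum())) % 3
            corrected, _ = smooth_correct(noisy, pos)

            def length(mat):
                r, _, _ = pairwise_r_lod(mat)
                return sum(kosambi(min(r[i, i + 1], 0.49))
                           for i in range(mat.shape[0] - 1))

            shrunk += length(corrected) < length(noisy)
        assert shrunk == 3

    def test_unordered_positions_rejected(self):
        codes, pos = self._clean_block()
        with pytest.raises(ValueError):
            smooth_correct(codes, pos[::-1])


class TestImpute:
    def test_homogeneous_block_fill(self):
        codes = np.zeros((5, 1), dtype=np.int8)
        codes[2, 0] = -1
        out = knn_impute(codes, np.arange(5) * 2.0, k=3)
        assert out[2, 0] == 0

    def test_all_missing_individual_stays_missing(self):
        codes = np.full((5, 1), -1, dtype=np.int8)
        out = knn_impute(codes, np.arange(5) * 2.0)
        assert (out == -1).all()

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            knn_impute(np.zeros((2, 2), dtype=np.int8), np.arange(2.0), k=0)

    def test_dense_map_masked_recovery_above_90pct(self):
        # study-like density (~2 cM between markers), clean genotypes
        cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(100.0,),
                        markers_per_chrom=(50,), n_individuals=130,
                        marker_positions=(np.linspace(0, 100, 50),),
                        polymorphic_fraction=1.0, seed=26)
        truth = simulate_meioses(cfg)
        g = truth.genotypes.to_numpy()
        pos = truth.positions["cM"].to_numpy()
        rng = np.random.default_rng(4)
        mask = rng.random(g.shape) < 0.10
        gm = g.copy()
        gm[mask] = -1
        imp = knn_impute(gm, pos, k=5)
        acc = ((imp == g) & mask).sum() / mask.sum()
        assert acc > 0.90

    def test_posterior_impute_fills_from_chain(self):
        from slafmap.genotype_calling import genotype_likelihoods
        codes = np.zeros((5, 2), dtype=np.int8)
        codes[:, 1] = 2
        gl = np.zeros((5, 2, 3))
        gl[codes == 0] = [0.98, 0.01, 0.01]
        gl[codes == 2] = [0.01, 0.01, 0.98]
        codes[2, 0] = -1
        gl[2, 0] = [1 / 3] * 3
        out = posterior_impute(codes, np.full(4, 0.02), gl)
        assert out[2, 0] == 0 and out[2, 1] == 2


class TestInsertSkewed:
    def _framework(self, positions, codes, ids=None):
        ids = ids or [f"f{i}" for i in range(len(positions))]
        return LinkageGroup(
            lg_id=1, marker_ids=ids, positions=np.asarray(positions, float),
            adjacent_r=np.array([kosambi_inverse(d)
                                 for d in np.diff(positions)]),
        )

    def test_identical_marker_colocates(self, small_truth):
        codes = small_truth.genotypes.to_numpy()[:10]
        pos = small_truth.positions["cM"].to_numpy()[:10]
        group = self._framework(pos - pos[0], codes)
        ext, unplaced = insert_skewed(group, codes, codes[4:5], ["acc"],
                                      lod_threshold=3.0)
        assert unplaced == []
        k = ext.marker_ids.index("acc")
        f4 = ext.marker_ids.index("f4")
        assert abs(ext.positions[k] - ext.positions[f4]) <= 1.0

    def test_framework_order_unchanged(self, small_truth):
        codes = small_truth.genotypes.to_numpy()[:10]
        pos = small_truth.positions["cM"].to_numpy()[:10]
        group = self._framework(pos - pos[0], codes)
        ext, _ = insert_skewed(group, codes, codes[3:6], ["a1", "a2", "a3"],
                               lod_threshold=3.0)
        kept = [m for m in ext.marker_ids if m.startswith("f")]
        assert kept == group.marker_ids
        fw_pos = [p for m, p in zip(ext.marker_ids, ext.positions)
                  if m.startswith("f")]
        assert np.allclose(np.diff(fw_pos), np.diff(group.positions), atol=1e-9)

    def test_unlinked_marker_left_unplaced(self, small_truth):
        codes = small_truth.genotypes.to_numpy()[:10]
        pos = small_truth.positions["cM"].to_numpy()[:10]
        group = self._framework(pos - pos[0], codes)
        rng = np.random.default_rng(5)
        noise = rng.integers(0, 3, size=(1, codes.shape[1])).astype(np.int8)
        ext, unplaced = insert_skewed(group, codes, noise, ["junk"],
                                      lod_threshold=5.0)
        assert unplaced == ["junk"]
        assert "junk" not in ext.marker_ids

    def test_midpoint_placement_recovery(self):
        # accessory marker truly midway between framework markers 10 cM apart
        hits = 0
        for seed in range(10):
            cfg = SimConfig(n_chromosomes=1, chrom_lengths_cM=(60.0,),
                            markers_per_chrom=(13,), n_individuals=130,
                            marker_positions=(np.arange(13) * 5.0,),
                            polymorphic_fraction=1.0, seed=40 + seed)
            truth = simulate_meioses(cfg)
            codes = truth.genotypes.to_numpy()
            fw_idx = list(range(0, 13, 2))     # every 10 cM
            acc_idx = 5                        # at 25 cM, midway of (20, 30)
            group = self._framework(np.array(fw_idx) * 5.0, codes[fw_idx])
            ext, unplaced = insert_skewed(group, codes[fw_idx],
                                          codes[acc_idx:acc_idx + 1], ["acc"],
                                          lod_threshold=3.0)
            assert not unplaced
            p = ext.positions[ext.marker_ids.index("acc")]
            hits += 20.0 <= p <= 30.0
        assert hits >= 9
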