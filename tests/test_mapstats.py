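import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pcfdc import (
    BinaryMask,
    CanonicalAtlas,
    NetworkMap,
    TemplateGrid,
    Volume3D,
    cdf_cutoff_values,
    cohens_d_paired,
    dice,
    friedman_test,
    is_pure_wm,
    map_mean_sd,
    nci,
    paired_voxelwise_test,
    spatial_correlation,
    two_sample_voxelwise_test,
    voxelwise_behaviour_correlation,
    wilcoxon_signed_rank,
    wm_ratio,
)

from conftest import correlated_vectors


def _vol(grid, flat):
    return Volume3D(grid, np.asarray(flat, float).reshape(grid.shape))


def _mask(grid, flat):
    return BinaryMask(grid, np.asarray(flat, int).reshape(grid.shape))


GRID4 = TemplateGrid.isotropic((1, 1, 4))


class TestCdfCutoffs:
    def test_constant_positive_map(self, grid8):
        m = NetworkMap(grid8, np.full(grid8.shape, 0.7), "rmap")
        np.testing.assert_allclose(cdf_cutoff_values(m), 0.7)

    def test_hand_percentile_and_monotonicity(self):
        grid = TemplateGrid.isotropic((1, 10, 10))
        m = NetworkMap(grid, np.arange(1.0, 101.0).reshape(grid.shape), "rmap")
        vals = cdf_cutoff_values(m)
        assert vals[2] == pytest.approx(50.5)  # P50 of 1..100, linear interpolation
        assert (np.diff(vals) >= 0).all()

    def test_negatives_and_zeros_masked(self):
        m = NetworkMap(GRID4, np.array([-1.0, 0.0, 2.0, 4.0]).reshape(1, 1, 4), "rmap")
        np.testing.assert_allclose(cdf_cutoff_values(m, [0, 100]), [2.0, 4.0])
        neg = NetworkMap(GRID4, np.full((1, 1, 4), -1.0), "rmap")
        with pytest.raises(ValueError, match="positive"):
            cdf_cutoff_values(neg)


class TestMapMeanSd:
    def test_hand_examples(self):
        m = NetworkMap(GRID4, np.array([0.1, 0.3, -0.2, 0.0]).reshape(1, 1, 4), "rmap")
        mean, sd, n = map_mean_sd(m, 0.0)
        assert (mean, n) == (pytest.approx(0.2), 2)
        mean, sd, n = map_mean_sd(m, 0.2)
        assert (mean, sd, n) == (pytest.approx(0.3), 0.0, 1)
        mean, sd, n = map_mean_sd(m, 5.0)
        assert n == 0 and np.isnan(mean)


class TestSpatialCorrelationAndNci:
    def test_identity_and_negation(self, grid8):
        v = Volume3D(grid8, np.random.default_rng(0).normal(size=grid8.shape))
        assert spatial_correlation(v, v) == pytest.approx(1.0)
        neg = Volume3D(grid8, -v.values)
        assert spatial_correlation(v, neg) == pytest.approx(-1.0)

    def test_hand_pearson(self):
        m = _vol(GRID4, [1, 2, 3, 4])
        t = _vol(GRID4, [1, 0, 1, 0])
        assert spatial_correlation(m, t) == pytest.approx(-0.4472, abs=1e-4)

    def _exact_atlas(self, corrs):
        vecs = correlated_vectors(corrs, length=27, rng_seed=4)
        grid = TemplateGrid.isotropic((3, 3, 3))
        m = _vol(grid, vecs[0])
        atlas = CanonicalAtlas(
            [(f"n{i}", _vol(grid, v)) for i, v in enumerate(vecs[1:])]
        )
        return m, atlas

    def test_nci_hand_fixture(self):
        m, atlas = self._exact_atlas([0.6, 0.1, 0.2, 0.3])
        res = nci(m, atlas)
        assert res.winner == "n0"
        assert res.winner_sc == pytest.approx(0.6)
        assert res.nci == pytest.approx(3.0, abs=1e-9)

    def test_nci_all_equal_is_one(self):
        m, atlas = self._exact_atlas([0.4, 0.4, 0.4])
        res = nci(m, atlas)
        assert res.nci == pytest.approx(1.0)

    def test_nci_exact_tie_broken_by_atlas_order(self):
        vecs = correlated_vectors([0.5], length=27, rng_seed=9)
        grid = TemplateGrid.isotropic((3, 3, 3))
        m = _vol(grid, vecs[0])
        tpl = _vol(grid, vecs[1])
        dup = Volume3D(grid, tpl.values.copy())
        res = nci(m, CanonicalAtlas([("first", tpl), ("second", dup)]))
        assert res.winner == "first"

    def test_nci_undefined_for_nonpositive_losing_mean(self):
        m, atlas = self._exact_atlas([0.5, -0.2, 0.1])
        res = nci(m, atlas)
        assert res.undefined and np.isnan(res.nci)
        assert res.winner == "n0"

    def test_nci_scale_invariance(self):
        m, atlas = self._exact_atlas([0.6, 0.1, 0.2, 0.3])
        scaled = Volume3D(m.grid, 7.5 * m.values)
        a, b = nci(m, atlas), nci(scaled, atlas)
        assert a.winner == b.winner
        assert a.nci == pytest.approx(b.nci)


class TestDiceAndWmRatio:
    def test_dice_examples(self, grid8):
        a = _mask(grid8, np.eye(8)[None].repeat(8, 0).reshape(-1)[: 8**3] > 0.5)
        assert dice(a, a) == 1.0
        base = np.zeros(grid8.shape, int)
        base[0, 0, 0] = base[0, 0, 1] = 1
        other = np.zeros(grid8.shape, int)
        other[0, 0, 1] = other[0, 0, 2] = 1
        assert dice(BinaryMask(grid8, base), BinaryMask(grid8, other)) == 0.5
        disjoint = np.zeros(grid8.shape, int)
        disjoint[5, 5, 5] = 1
        assert dice(BinaryMask(grid8, base), BinaryMask(grid8, disjoint)) == 0.0

    @given(st.integers(0, 2**20 - 1), st.integers(0, 2**20 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_dice_symmetry(self, bits_a, bits_b):
        grid = TemplateGrid.isotropic((4, 5, 1))
        a = np.array([int(b) for b in f"{bits_a | 1:020b}"]).reshape(4, 5, 1)
        b = np.array([int(x) for x in f"{bits_b | 1:020b}"]).reshape(4, 5, 1)
        ma, mb = BinaryMask(grid, a), BinaryMask(grid, b)
        assert dice(ma, mb) == dice(mb, ma)
        assert 0.0 <= dice(ma, mb) <= 1.0

    def test_wm_ratio_rules(self, grid8):
        wm_vals = np.zeros(grid8.shape, int)
        wm_vals[:4] = 1
        wm = BinaryMask(grid8, wm_vals)
        inside = np.zeros(grid8.shape, int)
        inside[0, 0, :3] = 1
        assert wm_ratio(BinaryMask(grid8, inside), wm) == 1.0
        assert is_pure_wm(BinaryMask(grid8, inside), wm)
        mixed = np.zeros(grid8.shape, int)
        mixed[3, 0, :5] = 1  # 5 in wm
        mixed[4, 0, :5] = 1  # 5 outside
        m = BinaryMask(grid8, mixed)
        assert wm_ratio(m, wm) == 0.5
        outside = np.zeros(grid8.shape, int)
        outside[6, 0, :4] = 1
        assert wm_ratio(BinaryMask(grid8, outside), wm) == 0.0


class TestWilcoxon:
    def test_hand_enumeration(self):
        stat, p, method = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0])
        assert (stat, method) == (6.0, "exact")
        assert p == pytest.approx(2 / 8)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])

    @pytest.mark.parametrize("n", range(4, 9))
    def test_exact_matches_sign_enumeration_oracle(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = rng.integers(-8, 9, size=n).astype(float)
            d[d == 0] = 1.0
            stat, p, method = wilcoxon_signed_rank(d, np.zeros(n))
            assert method == "exact"
            ranks = sps.rankdata(np.abs(d))
            mu = n * (n + 1) / 4
            obs = abs(ranks[d > 0].sum() - mu)
            count = sum(
                abs(sum(r for r, s in zip(ranks, signs) if s > 0) - mu) >= obs - 1e-12
                for signs in itertools.product([-1, 1], repeat=n)
            )
            assert p == pytest.approx(count / 2**n)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        _, p, _ = wilcoxon_signed_rank(x, y)
        assert p == pytest.approx(sps.wilcoxon(x, y, method="exact").pvalue)

    def test_normal_branch_close_to_exact(self):
        rng = np.random.default_rng(23)
        d = rng.normal(0.4, 1.0, size=13)
        d[d == 0] = 0.1
        z, p_norm, method = wilcoxon_signed_rank(d, np.zeros(13))
        assert method == "normal"
        ranks = sps.rankdata(np.abs(d))
        mu = 13 * 14 / 4
        obs = abs(ranks[d > 0].sum() - mu)
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        p_exact = np.mean(np.abs(totals - mu) >= obs - 1e-12)
        assert p_norm == pytest.approx(p_exact, abs=0.03)


class TestCohensDAndFriedman:
    def test_cohens_d_hand(self):
        assert cohens_d_paired([1, 3], [1, 1]) == pytest.approx(1 / np.sqrt(2))
        with pytest.raises(ValueError):
            cohens_d_paired([2, 3, 4, 5], [1, 2, 3, 4])  # constant differences

    def test_friedman_hand_fixture(self):
        data = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [0.1, 0.2, 0.3]])
        chi2, p = friedman_test(data)
        assert chi2 == pytest.approx(6.0)
        assert p == pytest.approx(float(sps.chi2.sf(6.0, 2)))

    def test_friedman_all_tied_rows(self):
        chi2, p = friedman_test(np.ones((4, 3)))
        assert chi2 == 0.0 and p == 1.0

    def test_friedman_matches_scipy_without_ties(self):
        rng = np.random.default_rng(31)
        data = rng.normal(size=(10, 4))
        chi2, p = friedman_test(data)
        ref = sps.friedmanchisquare(*data.T)
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)


def _maps(grid, arrays):
    return [NetworkMap(grid, a, "rmap") for a in arrays]


class TestPairedVoxelwise:
    def test_identical_inputs_not_significant(self, grid8):
        rng = np.random.default_rng(40)
        arrays = [rng.normal(size=grid8.shape) for _ in range(5)]
        res = paired_voxelwise_test(_maps(grid8, arrays), _maps(grid8, arrays),
                                    n_perm=30, rng_seed=0)
        assert res.a_gt_b.significant_mask.n_voxels == 0
        assert res.b_gt_a.significant_mask.n_voxels == 0

    def test_swapping_groups_swaps_contrasts(self, grid8):
        rng = np.random.default_rng(41)
        A = _maps(grid8, [rng.normal(size=grid8.shape) for _ in range(6)])
        B = _maps(grid8, [rng.normal(size=grid8.shape) for _ in range(6)])
        r1 = paired_voxelwise_test(A, B, n_perm=50, rng_seed=3)
        r2 = paired_voxelwise_test(B, A, n_perm=50, rng_seed=3)
        np.testing.assert_allclose(
            r1.a_gt_b.stat_map.values, r2.b_gt_a.stat_map.values, atol=1e-12
        )
        np.testing.assert_array_equal(
            r1.a_gt_b.fwe_p_map.values, r2.b_gt_a.fwe_p_map.values
        )

    def test_planted_offset_detected_in_roi(self, grid8):
        rng = np.random.default_rng(42)
        roi = np.zeros(grid8.shape, bool)
        roi[2:4, 2:4, 2:4] = True
        B_arr = [rng.normal(size=grid8.shape) for _ in range(10)]
        A_arr = [b + 3.0 * roi for b in B_arr]  # noise-free offset inside ROI
        A_arr = [a + 0.3 * rng.normal(size=grid8.shape) for a in A_arr]
        res = paired_voxelwise_test(_maps(grid8, A_arr), _maps(grid8, B_arr),
                                    n_perm=200, rng_seed=5)
        sig = res.a_gt_b.significant_mask.values
        assert sig[roi].mean() > 0.8
        assert sig[~roi].mean() < 0.05


class TestTwoSampleVoxelwise:
    def test_equal_groups_give_zero_t(self, grid8):
        rng = np.random.default_rng(50)
        arrays = [rng.normal(size=grid8.shape) for _ in range(4)]
        res = two_sample_voxelwise_test(_maps(grid8, arrays), _maps(grid8, arrays),
                                        n_perm=20, rng_seed=0)
        np.testing.assert_allclose(res.stat_map.values, 0.0, atol=1e-10)

    def test_planted_group_difference_detected(self, grid8):
        rng = np.random.default_rng(51)
        roi = np.zeros(grid8.shape, bool)
        roi[5:7, 5:7, 5:7] = True
        A = [rng.normal(size=grid8.shape) + 4.0 * roi for _ in range(8)]
        B = [rng.normal(size=grid8.shape) for _ in range(8)]
        res = two_sample_voxelwise_test(_maps(grid8, A), _maps(grid8, B),
                                        n_perm=200, rng_seed=1)
        sig = res.significant_mask.values
        assert sig[roi].mean() > 0.8
        assert sig[~roi].mean() < 0.05


class TestBehaviourCorrelation:
    def test_location_invariance_of_statistic(self, grid8):
        rng = np.random.default_rng(60)
        maps = _maps(grid8, [rng.normal(size=grid8.shape) for _ in range(8)])
        scores = rng.normal(size=8)
        sizes = rng.uniform(10, 20, size=8)
        r1 = voxelwise_behaviour_correlation(maps, scores, sizes, n_perm=20, rng_seed=2)
        r2 = voxelwise_behaviour_correlation(maps, scores + 100.0, sizes, n_perm=20, rng_seed=2)
        np.testing.assert_allclose(r1.stat_map.values, r2.stat_map.values, atol=1e-9)

    def test_noise_free_predictor_voxel_attains_max(self, grid8):
        rng = np.random.default_rng(61)
        arrays = [rng.normal(size=grid8.shape) for _ in range(10)]
        scores = np.array([a[1, 2, 3] for a in arrays])
        sizes = np.full(10, 12.0)
        res = voxelwise_behaviour_correlation(_maps(grid8, arrays), scores, sizes,
                                              n_perm=50, rng_seed=3)
        stat = np.abs(res.stat_map.values)
        assert np.unravel_index(np.argmax(stat), grid8.shape) == (1, 2, 3)

    def test_constant_scores_rejected(self, grid8):
        maps = _maps(grid8, [np.random.default_rng(i).normal(size=grid8.shape) for i in range(6)])
        with pytest.raises(ValueError, match="constant"):
            voxelwise_behaviour_correlation(maps, np.ones(6), np.arange(6.0), n_perm=5)
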