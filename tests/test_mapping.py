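import numpy as np
import pytest
from scipy import stats

import stimmap as sm
from stimmap.grid import VoxelGrid
from stimmap.mapping import (
    cog_to_mcp,
    extract_spots,
    heatmap_from_coverage,
    rmap_spearman,
    smooth_map,
    spatial_correlation,
    voxelwise_heatmap,
)


def make_pmap(grid, signed_p=None, p=None, t=None, defined=None):
    """Assemble a SignedPMap directly for cluster-extraction tests."""
    shape = grid.shape
    p = np.ones(shape) if p is None else p
    t = np.zeros(shape) if t is None else t
    sp = (1.0 - p) * np.sign(t) if signed_p is None else signed_p
    defined = np.ones(shape, dtype=bool) if defined is None else defined
    return sm.SignedPMap(
        grid=grid,
        t_value=t,
        p_value=p,
        signed_p=sp,
        coverage_count=np.zeros(shape, dtype=np.int32),
        defined_mask=defined,
        degenerate_mask=np.zeros(shape, dtype=bool),
        n_subjects=10,
    )


class TestVoxelwiseHeatmap:
    def test_hand_computed_two_voxel_example(self):
        # voxel A covered by outcomes {40, 20}, voxel B by {0, -20}:
        # pooled two-sample t at A is +2.828 (df 2), two-sided p 0.1056
        grid = VoxelGrid((2, 1, 1))
        covered = [np.array([0]), np.array([0]), np.array([1]), np.array([1])]
        outcomes = np.array([40.0, 20.0, 0.0, -20.0])
        pmap = heatmap_from_coverage(grid, covered, outcomes, min_coverage=2)
        assert pmap.t_value[0, 0, 0] == pytest.approx(2.8284271, abs=1e-6)
        assert pmap.p_value[0, 0, 0] == pytest.approx(0.105573, abs=1e-5)
        assert pmap.signed_p[0, 0, 0] == pytest.approx(0.894427, abs=1e-5)
        assert pmap.signed_p[1, 0, 0] == pytest.approx(-0.894427, abs=1e-5)

    def test_identical_outcomes_give_zero_signed_p(self):
        grid = VoxelGrid((2, 1, 1))
        covered = [np.array([0]), np.array([0]), np.array([1]), np.array([1])]
        pmap = heatmap_from_coverage(grid, covered, np.full(4, 20.0), min_coverage=2)
        assert np.all(pmap.signed_p == 0)
        assert pmap.degenerate_mask[pmap.defined_mask].all()

    def test_insufficient_coverage_flagged_undefined(self):
        grid = VoxelGrid((2, 1, 1))
        covered = [np.array([0]), np.array([1]), np.array([1]), np.array([1])]
        pmap = heatmap_from_coverage(grid, covered, np.array([1.0, 2, 3, 4]), min_coverage=2)
        assert not pmap.defined_mask[0, 0, 0]  # coverage 1 < 2
        assert not pmap.defined_mask[1, 0, 0]  # non-covering group has 1 < 2
        assert np.all(pmap.signed_p == 0)

    def test_matches_brute_force_ttest_oracle(self):
        # independent per-voxel oracle: scipy two-sample t on explicit groups
        rng = np.random.default_rng(42)
        grid = VoxelGrid((5, 5, 5))
        n = 6
        covered = [
            np.unique(rng.integers(0, grid.n_voxels, size=rng.integers(10, 60)))
            for _ in range(n)
        ]
        outcomes = rng.normal(20, 30, size=n)
        pmap = heatmap_from_coverage(grid, covered, outcomes, min_coverage=2)
        member = np.zeros((n, grid.n_voxels), dtype=bool)
        for i, idx in enumerate(covered):
            member[i, idx] = True
        for v in range(grid.n_voxels):
            inside = outcomes[member[:, v]]
            outside = outcomes[~member[:, v]]
            ijk = np.unravel_index(v, grid.shape)
            if len(inside) >= 2 and len(outside) >= 2:
                t, p = stats.ttest_ind(inside, outside, equal_var=True)
                assert pmap.t_value[ijk] == pytest.approx(t, abs=1e-12)
                assert pmap.p_value[ijk] == pytest.approx(p, abs=1e-12)
            else:
                assert not pmap.defined_mask[ijk]

    def test_subject_order_invariance(self, tiny_cohort):
        pmap = voxelwise_heatmap(tiny_cohort)
        reordered = sm.Cohort(grid=tiny_cohort.grid, subjects=tiny_cohort.subjects[::-1])
        pmap_r = voxelwise_heatmap(reordered)
        assert np.array_equal(pmap.signed_p, pmap_r.signed_p)

    def test_sign_equivariance_under_outcome_negation(self):
        grid = VoxelGrid((3, 1, 1))
        rng = np.random.default_rng(5)
        covered = [np.unique(rng.integers(0, 3, size=2)) for _ in range(6)]
        y = rng.normal(0, 10, 6)
        a = heatmap_from_coverage(grid, covered, y)
        b = heatmap_from_coverage(grid, covered, -y)
        assert np.allclose(a.signed_p, -b.signed_p)

    def test_too_few_subjects_rejected(self):
        grid = VoxelGrid((2, 1, 1))
        with pytest.raises(ValueError):
            heatmap_from_coverage(grid, [np.array([0])] * 3, np.ones(3))


class TestExtractSpots:
    def grid(self):
        return VoxelGrid((12, 12, 12))

    def blob_mask(self, grid, corner, size):
        vol = np.zeros(grid.shape, dtype=bool)
        vol[corner[0]:corner[0] + size[0], corner[1]:corner[1] + size[1], corner[2]:corner[2] + size[2]] = True
        return vol

    def test_single_positive_blob_found(self):
        grid = self.grid()
        sig = self.blob_mask(grid, (2, 2, 2), (5, 4, 3))  # 60 voxels
        pmap = make_pmap(grid, p=np.where(sig, 0.01, 0.5), t=np.where(sig, 2.0, 0.1))
        spots = extract_spots(pmap, min_cluster=50)
        assert len(spots) == 1
        assert spots[0].kind == "sweetspot" and spots[0].size == 60

    def test_blob_below_threshold_ignored(self):
        grid = self.grid()
        sig = self.blob_mask(grid, (2, 2, 2), (5, 3, 3))  # 45 voxels
        pmap = make_pmap(grid, p=np.where(sig, 0.01, 0.5), t=np.where(sig, 2.0, 0.1))
        assert extract_spots(pmap, min_cluster=50) == []

    def test_exactly_min_cluster_excluded(self):
        grid = self.grid()
        sig = self.blob_mask(grid, (2, 2, 2), (5, 5, 2))  # exactly 50
        pmap = make_pmap(grid, p=np.where(sig, 0.01, 0.5), t=np.where(sig, 2.0, 0.1))
        assert extract_spots(pmap, min_cluster=50) == []  # strict >

    def test_positive_and_negative_blobs_split_by_sign(self):
        grid = self.grid()
        pos = self.blob_mask(grid, (1, 1, 1), (4, 4, 4))  # 64
        neg = self.blob_mask(grid, (7, 7, 7), (4, 4, 4))  # 64
        t = np.where(pos, 2.0, np.where(neg, -2.0, 0.1))
        p = np.where(pos | neg, 0.01, 0.5)
        spots = extract_spots(make_pmap(grid, p=p, t=t), min_cluster=50)
        assert sorted(s.kind for s in spots) == ["sourspot", "sweetspot"]

    def test_cog_is_mean_world_coordinate(self):
        grid = self.grid()
        sig = self.blob_mask(grid, (2, 3, 4), (4, 4, 4))
        pmap = make_pmap(grid, p=np.where(sig, 0.01, 0.5), t=np.where(sig, 2.0, 0.1))
        spot = extract_spots(pmap, min_cluster=50)[0]
        expected = grid.index_to_world(np.argwhere(sig)).mean(axis=0)
        assert np.allclose(spot.cog, expected)


class TestCogToMcp:
    def test_template_sweetspot_offset(self):
        # reference COG and its offset from the midcommissural point
        offset = cog_to_mcp((-18.4, -7.3, -7.0), (0.0, -11.8, -3.3))
        assert np.allclose(offset, (-18.4, 4.5, -3.7))

    def test_origin_mcp_is_identity(self):
        assert np.allclose(cog_to_mcp((1.0, 2.0, 3.0), (0, 0, 0)), (1, 2, 3))

    def test_cog_equal_mcp_gives_zero(self):
        assert np.allclose(cog_to_mcp((1.0, 2.0, 3.0), (1.0, 2.0, 3.0)), (0, 0, 0))


class TestSmoothMap:
    def test_constant_volume_unchanged(self):
        vol = np.full((7, 7, 7), 3.25)
        assert np.allclose(smooth_map(vol, 3), vol)

    def test_unit_impulse_spreads_to_27_voxels(self):
        vol = np.zeros((7, 7, 7))
        vol[3, 3, 3] = 1.0
        sm3 = smooth_map(vol, 3)
        assert np.count_nonzero(sm3) == 27
        assert sm3[3, 3, 3] == pytest.approx(1 / 27)
        assert sm3.sum() == pytest.approx(1.0)

    def test_kernel_one_is_identity(self):
        vol = np.random.default_rng(0).normal(size=(5, 5, 5))
        assert np.array_equal(smooth_map(vol, 1), vol)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            smooth_map(np.zeros((5, 5, 5)), 2)


class TestRMap:
    def test_perfect_monotone_gives_rho_one(self):
        grid = VoxelGrid((2, 1, 1))
        mags = np.arange(5.0)[:, None, None, None] * np.ones((1, 2, 1, 1))
        y = np.array([1.0, 3.0, 4.0, 8.0, 9.0])
        rmap = rmap_spearman(mags, y, grid)
        assert np.allclose(rmap.values, 1.0)

    def test_ties_match_scipy_oracle(self):
        grid = VoxelGrid((1, 1, 1))
        mags = np.array([1.0, 2.0, 2.0, 3.0, 4.0]).reshape(5, 1, 1, 1)
        y = np.array([2.0, 1.0, 5.0, 4.0, 3.0])
        rmap = rmap_spearman(mags, y, grid)
        expected = stats.spearmanr(mags.ravel(), y).statistic
        assert rmap.values[0, 0, 0] == pytest.approx(expected, abs=1e-12)

    def test_constant_outcomes_all_undefined(self):
        grid = VoxelGrid((2, 1, 1))
        mags = np.random.default_rng(0).random((5, 2, 1, 1))
        rmap = rmap_spearman(mags, np.full(5, 7.0), grid)
        assert not rmap.defined_mask.any()
        assert np.all(rmap.values == 0)

    def test_tied_magnitudes_flagged_undefined(self):
        grid = VoxelGrid((2, 1, 1))
        mags = np.ones((5, 2, 1, 1))
        mags[:, 1] = np.arange(5).reshape(5, 1, 1)
        rmap = rmap_spearman(mags, np.arange(5.0), grid)
        assert not rmap.defined_mask[0, 0, 0]
        assert rmap.defined_mask[1, 0, 0]


class TestSpatialCorrelation:
    def test_self_correlation_is_one(self):
        a = np.random.default_rng(1).normal(size=(4, 4, 4))
        r, p, n = spatial_correlation(a, a)
        assert r == pytest.approx(1.0)
        assert n == 64

    def test_negated_map_gives_minus_one(self):
        a = np.random.default_rng(1).normal(size=(4, 4, 4))
        r, _, _ = spatial_correlation(a, -a)
        assert r == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        a = np.array([1.0, 2.0, 4.0, 3.0]).reshape(4, 1, 1)
        b = np.array([2.0, 1.0, 5.0, 6.0]).reshape(4, 1, 1)
        r, _, _ = spatial_correlation(a, b)
        am, bm = a.ravel() - a.mean(), b.ravel() - b.mean()
        expected = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spatial_correlation(np.ones((3, 3, 3)), np.random.default_rng(0).normal(size=(3, 3, 3)))
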