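import numpy as np
import pytest

import stimmap as sm
from stimmap.grid import VoxelGrid
from stimmap.prediction import (
    InterferenceHistogram,
    _bin_edges,
    cog_distance_regression,
    fit_outcome_model,
    interference_histogram,
    loo_histograms,
    loocv_predict,
    mean_r_prediction,
    stimparams_regression,
)
from stimmap.vta import VTAMask

from conftest import make_tiny_cohort


def pmap_with_values(grid, values, defined=None):
    values = np.asarray(values, dtype=float)
    defined = np.ones(grid.shape, dtype=bool) if defined is None else defined
    return sm.SignedPMap(
        grid=grid,
        t_value=np.sign(values),
        p_value=1.0 - np.abs(values),
        signed_p=np.where(defined, values, 0.0),
        coverage_count=np.zeros(grid.shape, dtype=np.int32),
        defined_mask=defined,
        degenerate_mask=np.zeros(grid.shape, dtype=bool),
        n_subjects=9,
    )


def mask_of(grid, flat_indices):
    idx = np.stack(np.unravel_index(np.asarray(flat_indices, int), grid.shape), axis=1)
    return VTAMask(grid, idx)


class TestInterferenceHistogram:
    def test_bin_edge_arithmetic(self):
        # {+0.9, +0.9, -0.9}: one count in bin 1 ([-1, -0.8667)), two in bin 15
        grid = VoxelGrid((3, 1, 1))
        pmap = pmap_with_values(grid, np.array([0.9, 0.9, -0.9]).reshape(3, 1, 1))
        pair = (mask_of(grid, [0, 1]), mask_of(grid, [2]))
        hist = interference_histogram(pmap, pair, n_bins=15)
        assert hist.counts[0] == 1 and hist.counts[14] == 2
        assert hist.total == 3

    def test_zero_values_land_in_middle_bin(self):
        grid = VoxelGrid((4, 1, 1))
        pmap = pmap_with_values(grid, np.zeros((4, 1, 1)))
        hist = interference_histogram(pmap, (mask_of(grid, [0, 1]), mask_of(grid, [2, 3])), 15)
        assert hist.counts[7] == 4  # bin 8: [-0.0667, +0.0667)
        assert hist.counts.sum() == 4

    def test_counts_conserve_multiplicity(self, nf_heatmap, noise_free_cohort):
        s = noise_free_cohort.subjects[0]
        hist = interference_histogram(nf_heatmap, s.vta_pair(), 15)
        assert hist.total == sum(len(m) for m in s.vta_pair())

    def test_plus_one_falls_in_last_bin(self):
        grid = VoxelGrid((1, 1, 1))
        pmap = pmap_with_values(grid, np.array([[[1.0]]]))
        hist = interference_histogram(pmap, (mask_of(grid, [0]), mask_of(grid, [0])), 15)
        assert hist.counts[14] == 2

    def test_undefined_sampled_as_zero_or_excluded(self):
        grid = VoxelGrid((2, 1, 1))
        defined = np.array([True, False]).reshape(2, 1, 1)
        pmap = pmap_with_values(grid, np.array([0.9, 0.9]).reshape(2, 1, 1), defined)
        pair = (mask_of(grid, [0]), mask_of(grid, [1]))
        h_zero = interference_histogram(pmap, pair, 15)
        assert h_zero.counts[7] == 1 and h_zero.counts[14] == 1
        h_excl = interference_histogram(pmap, pair, 15, undefined="exclude")
        assert h_excl.total == 1

    def test_empty_vta_rejected(self):
        grid = VoxelGrid((2, 1, 1))
        pmap = pmap_with_values(grid, np.zeros((2, 1, 1)))
        with pytest.raises(ValueError, match="empty"):
            interference_histogram(pmap, (mask_of(grid, [0]), VTAMask(grid, np.empty((0, 3), int))), 15)


class TestLooHistograms:
    def test_one_histogram_per_subject_with_fold_ids(self, tiny_cohort):
        hists = loo_histograms(tiny_cohort, n_bins=9)
        assert len(hists) == len(tiny_cohort)
        assert [h.fold_id for h in hists] == list(range(len(tiny_cohort)))

    def test_fold_heatmap_differs_from_full_map(self, tiny_cohort):
        full = sm.voxelwise_heatmap(tiny_cohort)
        fold0 = sm.voxelwise_heatmap(tiny_cohort, exclude={tiny_cohort.subjects[0].subject_id})
        assert not np.array_equal(full.signed_p, fold0.signed_p)

    def test_matches_recompute_from_scratch(self, tiny_cohort):
        hists = loo_histograms(tiny_cohort, n_bins=9)
        s3 = tiny_cohort.subjects[3]
        fold_map = sm.voxelwise_heatmap(tiny_cohort, exclude={s3.subject_id})
        direct = interference_histogram(fold_map, s3.vta_pair(), 9)
        assert np.array_equal(hists[3].counts, direct.counts)

    def test_fold_invariant_to_order_of_remaining(self, tiny_cohort):
        hists = loo_histograms(tiny_cohort, n_bins=9)
        reordered = sm.Cohort(
            grid=tiny_cohort.grid,
            subjects=[tiny_cohort.subjects[0]] + tiny_cohort.subjects[:0:-1],
        )
        hists_r = loo_histograms(reordered, n_bins=9)
        assert np.array_equal(hists[0].counts, hists_r[0].counts)

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            loo_histograms(make_tiny_cohort(n=4), n_bins=9)


def make_hists(counts_matrix, n_bins):
    edges = _bin_edges(n_bins)
    return [
        InterferenceHistogram(f"S{i}", n_bins, edges, np.asarray(c, int))
        for i, c in enumerate(counts_matrix)
    ]


class TestFitOutcomeModel:
    def test_perfect_linear_outcome_recovers_r2_one(self):
        rng = np.random.default_rng(0)
        counts = np.zeros((8, 5), dtype=int)
        counts[:, 2] = rng.integers(1, 30, 8)
        hists = make_hists(counts, 5)
        y = 3.0 * counts[:, 2] + 7.0
        model = fit_outcome_model(hists, y)
        assert model.r_squared == pytest.approx(1.0)
        assert model.coefficients[2] == pytest.approx(3.0)

    def test_identical_histograms_reduce_to_intercept(self):
        counts = np.tile([1, 2, 3, 4, 5], (8, 1))
        y = np.random.default_rng(1).normal(10, 5, 8)
        with pytest.warns(UserWarning, match="rank-deficient"):
            model = fit_outcome_model(make_hists(counts, 5), y)
        assert model.r_squared == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(model.predict(make_hists(counts[:1], 5)), y.mean())

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 20, size=(8, 3))
        y = rng.normal(0, 10, 8)
        model = fit_outcome_model(make_hists(counts, 3), y)
        X = np.column_stack([np.ones(8), counts.astype(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert model.intercept == pytest.approx(beta[0], abs=1e-8)
        assert np.allclose(model.coefficients, beta[1:], atol=1e-8)

    def test_saturated_fit_has_nan_f_pvalue(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 20, size=(5, 4))
        model = fit_outcome_model(make_hists(counts, 4), rng.normal(size=5))
        assert np.isnan(model.f_pvalue)


class TestLoocv:
    def test_recovers_linear_generation(self):
        # outcomes exactly linear in the counts: near-perfect prediction
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 25, size=(20, 5))
        w = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        y = counts @ w + 5.0
        cv = loocv_predict(make_hists(counts, 5), y)
        assert cv.pearson_r > 0.95

    def test_boundary_sample_sizes(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 25, size=(7, 5))
        y = rng.normal(size=7)
        loocv_predict(make_hists(counts, 5), y)  # n = n_bins + 2 runs
        with pytest.raises(ValueError):
            loocv_predict(make_hists(counts[:6], 5), y[:6])

    def test_permutation_null_destroys_prediction(self, nf_histograms, noise_free_cohort):
        rng = np.random.default_rng(123)
        y = noise_free_cohort.outcomes()
        rs = []
        for _ in range(20):
            cv = loocv_predict(nf_histograms, rng.permutation(y))
            rs.append(abs(cv.pearson_r))
        assert np.mean(rs) < 0.3

    def test_loocv_training_excludes_held_out_outcome(self, nf_histograms, noise_free_cohort):
        # altering subject 0's outcome must not move its own prediction
        y = noise_free_cohort.outcomes()
        base = loocv_predict(nf_histograms, y)
        y2 = y.copy()
        y2[0] = 0.0
        altered = loocv_predict(nf_histograms, y2)
        assert altered.predicted[0] == base.predicted[0]

    def test_full_fit_r2_bounds_loocv_r2(self, default_field):
        # in-sample fit should beat out-of-sample correlation almost always
        wins = 0
        for seed in range(8):
            cohort = sm.simulate_cohort(
                sm.CohortConfig(n_subjects=20, seed=seed, noise_sd=10.0), default_field
            )
            hists = loo_histograms(cohort, n_bins=9)
            y = cohort.outcomes()
            model = fit_outcome_model(hists, y)
            cv = loocv_predict(hists, y)
            wins += model.r_squared >= cv.pearson_r**2
        assert wins >= 7

    def test_nine_bin_variant_also_fits_noise_free_data(self, noise_free_cohort):
        hists9 = loo_histograms(noise_free_cohort, n_bins=9)
        model9 = fit_outcome_model(hists9, noise_free_cohort.outcomes())
        assert model9.r_squared > 0.9


class TestBaselines:
    def test_cog_distance_exact_linear_relation(self, default_field):
        cohort = make_tiny_cohort(n=10, seed=4)
        cog = (-18.4, -7.3, -7.0)
        from stimmap.prediction import _active_contact_coords

        dists = np.array(
            [np.linalg.norm(_active_contact_coords(s) - np.asarray(cog), axis=1).mean()
             for s in cohort.subjects]
        )
        for s, d in zip(cohort.subjects, dists):
            s.score_pre = 50.0
            s.score_post = 50.0 * (1 - (-2.0 * d + 30.0) / 100.0)
        r2, p, slope = cog_distance_regression(cohort, cog)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(-2.0)

    def test_cog_distance_null_not_significant(self):
        cohort = make_tiny_cohort(n=40, seed=5)
        rng = np.random.default_rng(6)
        for s in cohort.subjects:  # outcomes independent of geometry
            s.score_pre = 50.0
            s.score_post = 50.0 * (1 - rng.normal(15, 30) / 100.0)
        r2, p, _ = cog_distance_regression(cohort, (-18.4, -7.3, -7.0))
        assert p > 0.05

    def test_stimparams_perfect_amplitude_relation(self):
        cohort = make_tiny_cohort(n=10, seed=7)
        for s in cohort.subjects:
            amp = np.mean([st.amplitude for st in s.settings.values()])
            s.score_pre = 50.0
            s.score_post = 50.0 * (1 - 2.0 * amp / 100.0)
        with pytest.warns(UserWarning, match="constant"):
            r2, p = stimparams_regression(cohort)
        assert r2 == pytest.approx(1.0)

    def test_stimparams_all_constant_rejected(self):
        cohort = make_tiny_cohort(n=6, seed=8, amplitude_range=(2.0, 2.0))
        with pytest.raises(ValueError, match="constant"), pytest.warns(UserWarning):
            stimparams_regression(cohort)

    def test_stimparams_matches_normal_equations(self):
        cohort = make_tiny_cohort(n=10, seed=9)
        with pytest.warns(UserWarning, match="constant"):
            r2, p = stimparams_regression(cohort)
        amps = np.array(
            [np.mean([st.amplitude for st in s.settings.values()]) for s in cohort.subjects]
        )
        y = cohort.outcomes()
        X = np.column_stack([np.ones(10), amps])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_direct = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2 == pytest.approx(r2_direct, abs=1e-10)

    def test_mean_r_prediction_recovers_monotone_cohort(self, noise_free_cohort):
        cv = mean_r_prediction(noise_free_cohort)
        assert cv.pearson_r > 0.5
        assert cv.p_value < 0.05

    def test_mean_r_constant_scores_surface_error(self, default_field):
        cohort = make_tiny_cohort(n=6, seed=10)
        for s in cohort.subjects:  # identical outcomes -> constant scores
            s.score_pre, s.score_post = 50.0, 40.0
        with pytest.raises(ValueError, match="constant"):
            mean_r_prediction(cohort)
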