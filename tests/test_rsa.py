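"""Searchlights, noise normalization, RDMs, smoothing, cluster inference."""

import numpy as np
import pytest
from scipy import stats

from episcale import (build_searchlights, group_cluster_mass,
                      model_correlation, pairwise_distances, prewhiten,
                      smooth_map, between_episode_model, within_episode_model,
                      within_episode_pairs, between_episode_pairs)
from episcale.rsa import shrinkage_covariance, _inv_sqrt


class TestSearchlights:
    def test_dense_mask_exact_size_and_radius(self):
        mask = np.ones((8, 8, 8), dtype=bool)
        sls, skipped = build_searchlights(mask)
        assert len(sls) == 512 and not skipped
        for sl in sls:
            assert sl.members.shape == (10, 3)
            d = np.linalg.norm((sl.members - np.array(sl.center)) * 3.0,
                               axis=1)
            assert d.max() <= 10.0
            assert tuple(sl.members[np.argmin(d)]) == sl.center

    def test_tiny_mask_rejected(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[:3, 0, 0] = True          # 3 voxels < 10
        with pytest.raises(ValueError, match="fewer than"):
            build_searchlights(mask)

    def test_sparse_mask_centers_skipped_with_report(self):
        mask = np.zeros((20, 20, 20), dtype=bool)
        mask[::4, ::4, ::4] = True     # 12 mm spacing: nothing within 10 mm
        sls, skipped = build_searchlights(mask)
        assert len(sls) == 0
        assert len(skipped) == 125

    def test_border_searchlights_nonspherical_but_full(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        sls, skipped = build_searchlights(mask)
        corner = next(sl for sl in sls if sl.center == (0, 0, 0))
        assert corner.members.shape == (10, 3)

    def test_deterministic(self):
        mask = np.ones((6, 6, 6), dtype=bool)
        a, _ = build_searchlights(mask)
        b, _ = build_searchlights(mask)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.members, y.members)


class TestPrewhiten:
    def test_iid_residuals_leave_patterns_nearly_unchanged(self, rng):
        betas = rng.normal(0, 1, (6, 5))
        residuals = rng.normal(0, 1, (5000, 5))
        W = prewhiten(betas, residuals)
        np.testing.assert_allclose(W, betas, atol=0.1)

    def test_diagonal_covariance_standardizes_voxels(self, rng):
        scales = np.array([1.0, 2.0, 4.0])
        residuals = rng.normal(0, 1, (8000, 3)) * scales
        betas = np.eye(3) * scales
        W = prewhiten(betas, residuals)
        np.testing.assert_allclose(np.diag(W), 1.0, rtol=0.1)

    def test_two_voxel_closed_form_inverse_sqrt(self, rng):
        residuals = rng.normal(0, 1, (500, 2))
        residuals[:, 1] = 0.8 * residuals[:, 0] + 0.6 * residuals[:, 1]
        S = shrinkage_covariance(residuals)
        # closed-form 2x2 principal square root: sqrt(S) = (S + sqrt(det) I)/s
        det = np.sqrt(np.linalg.det(S))
        s = np.sqrt(np.trace(S) + 2 * det)
        sqrtS = (S + det * np.eye(2)) / s
        expected = np.linalg.inv(sqrtS)
        np.testing.assert_allclose(_inv_sqrt(S), expected, atol=1e-8)

    def test_whitened_distance_equals_mahalanobis(self, rng):
        residuals = rng.normal(0, 1, (400, 4))
        residuals[:, 0] += residuals[:, 1]
        betas = rng.normal(0, 1, (3, 4))
        S = shrinkage_covariance(residuals)
        W = prewhiten(betas, residuals)
        d_white = np.sum((W[0] - W[1]) ** 2)
        diff = betas[0] - betas[1]
        d_mahal = diff @ np.linalg.inv(S) @ diff
        assert d_white == pytest.approx(d_mahal, rel=1e-8)


class TestRdm:
    def test_identical_patterns_zero(self):
        P = np.ones((4, 6))
        pairs = np.array([[0, 1], [2, 3]])
        np.testing.assert_allclose(pairwise_distances(P, pairs), 0.0)

    def test_orthogonal_unit_patterns_distance_two(self):
        P = np.eye(3)
        d = pairwise_distances(P, np.array([[0, 1], [0, 2], [1, 2]]))
        np.testing.assert_allclose(d, 2.0)

    def test_toy_case_matches_brute_force(self, rng):
        P = rng.normal(0, 1, (5, 7))
        pairs = np.array([(i, j) for i in range(5) for j in range(i + 1, 5)])
        d = pairwise_distances(P, pairs)
        for (i, j), val in zip(pairs, d):
            assert val == pytest.approx(np.sum((P[i] - P[j]) ** 2))

    def test_pair_index_layout(self):
        pairs = within_episode_pairs(3, n_objects=5)
        assert pairs.shape == (30, 2)          # 10 pairs per episode
        assert np.all(pairs[:, 0] // 5 == pairs[:, 1] // 5)
        bp = between_episode_pairs(48)
        assert bp.shape == (48 * 47 // 2, 2)

    def test_model_rdm_values(self):
        scaling = np.array([0.8, 1.0, 1.3])
        pairs = within_episode_pairs(3, n_objects=5)
        m = within_episode_model(scaling, pairs, 5)
        assert m[0] == pytest.approx(-0.2)     # compressed episode
        assert m[-1] == pytest.approx(0.3)     # expanded episode
        exp = np.array([0.0, 0.5, 0.2])
        bm = between_episode_model(exp, between_episode_pairs(3))
        np.testing.assert_allclose(bm, [0.5, 0.2, 0.3])


class TestModelCorrelation:
    def test_perfect_rank_agreement(self, rng):
        model = rng.normal(0, 1, 30)
        rho = model_correlation(2.0 * model + 5.0, model)
        assert rho[0] == pytest.approx(1.0)
        rho = model_correlation(-model, model)
        assert rho[0] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, rng):
        model = rng.normal(0, 1, 40)
        obs = rng.normal(0, 1, 40)
        a = model_correlation(obs, model)[0]
        b = model_correlation(obs, np.exp(model))[0]
        assert a == pytest.approx(b)

    def test_constant_model_flagged_nan(self):
        assert np.isnan(model_correlation(np.arange(10.0), np.ones(10))[0])

    def test_partial_correlation_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg
        cov = rng.normal(0, 1, 50)
        model = 0.7 * cov + rng.normal(0, 0.5, 50)
        obs = 0.5 * cov + 0.3 * model + rng.normal(0, 0.5, 50)
        ours = model_correlation(obs, model, covariate=cov)[0]
        df = pd.DataFrame(dict(obs=obs, model=model, cov=cov))
        ref = pg.partial_corr(df, x="model", y="obs", covar="cov",
                              method="spearman").r.iloc[0]
        assert ours == pytest.approx(ref, abs=1e-6)


class TestSmoothing:
    def test_constant_map_unchanged(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        vol = np.full((10, 10, 10), 3.3)
        out = smooth_map(vol, mask)
        np.testing.assert_allclose(out, 3.3, rtol=1e-6)

    def test_delta_recovers_kernel_width(self):
        mask = np.ones((31, 31, 31), dtype=bool)
        vol = np.zeros((31, 31, 31))
        vol[15, 15, 15] = 1.0
        out = smooth_map(vol, mask, fwhm_mm=6.0, voxel_size_mm=3.0)
        profile = out[:, 15, 15]
        half = profile.max() / 2
        above = np.where(profile >= half)[0]
        fwhm_vox = above[-1] - above[0] + 1
        assert fwhm_vox * 3.0 == pytest.approx(6.0, abs=3.0)

    def test_mass_preserved_in_interior(self):
        mask = np.ones((21, 21, 21), dtype=bool)
        rng = np.random.default_rng(0)
        vol = rng.normal(0, 1, (21, 21, 21))
        out = smooth_map(vol, mask)
        assert out[5:16, 5:16, 5:16].mean() == pytest.approx(
            vol[5:16, 5:16, 5:16].mean(), abs=0.15)


class TestClusterInference:
    def test_sign_flip_symmetry(self, rng):
        from episcale.rsa import _t_map
        maps = rng.normal(0, 1, (8, 6, 6, 6))
        t_pos = _t_map(maps.reshape(8, -1))
        t_neg = _t_map(-maps.reshape(8, -1))
        np.testing.assert_allclose(t_neg, -t_pos, atol=1e-10)

    def test_planted_blob_detected(self, rng):
        mask = np.ones((10, 10, 10), dtype=bool)
        maps = rng.normal(0, 1, (12, 10, 10, 10))
        maps[:, 3:7, 3:7, 3:7] += 3.0
        res = group_cluster_mass(maps, mask, seed=0)
        assert len(res.cluster_masses) >= 1
        assert res.cluster_p.min() <= 0.05
        lab = res.cluster_labels[5, 5, 5]
        assert lab in res.significant_clusters

    def test_pure_noise_rarely_significant(self, rng):
        mask = np.ones((8, 8, 8), dtype=bool)
        maps = rng.normal(0, 1, (8, 8, 8, 8))
        res = group_cluster_mass(maps, mask, seed=1)
        assert res.n_permutations == 256     # full enumeration at n = 8
        assert len(res.significant_clusters) == 0

    def test_too_few_subjects_rejected(self, rng):
        mask = np.ones((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="subjects"):
            group_cluster_mass(rng.normal(0, 1, (4, 4, 4, 4)), mask)
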