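"""Voxelwise GLM, cluster formation, smoothness, and corrected p-values."""

import numpy as np
import pandas as pd
import pytest
import scipy.ndimage
import scipy.stats

from rehodyn import ScalarMap, default_affine
from rehodyn.inference import (
    build_design,
    cluster_pvalues,
    dice_coefficient,
    estimate_smoothness,
    fit_glm_voxelwise,
    grf_cluster_p,
    group_difference_analysis,
    permutation_max_cluster_null,
    threshold_and_cluster,
)
from rehodyn.synthetic import null_map_stack


def _group_design(n_a, n_b):
    return pd.DataFrame({
        "intercept": np.ones(n_a + n_b),
        "group": np.r_[np.ones(n_a), np.zeros(n_b)],
    })


class TestGlm:
    def test_equals_two_sample_t(self, rng):
        n_a, n_b = 9, 7
        stack = rng.standard_normal((n_a + n_b, 5, 4, 3))
        tmap, _, df = fit_glm_voxelwise(stack, _group_design(n_a, n_b))
        t_oracle = scipy.stats.ttest_ind(stack[:n_a], stack[n_a:], axis=0).statistic
        np.testing.assert_allclose(tmap.data, t_oracle, atol=1e-10)
        assert df == n_a + n_b - 2

    def test_constant_group_column_rejected(self, rng):
        stack = rng.standard_normal((10, 3, 3, 3))
        design = pd.DataFrame({"intercept": np.ones(10), "group": np.ones(10)})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_glm_voxelwise(stack, design)

    def test_error_names_collinear_columns(self, rng):
        n = 12
        age = rng.standard_normal(n)
        design = pd.DataFrame({
            "intercept": np.ones(n),
            "group": np.r_[np.ones(6), np.zeros(6)],
            "age": age,
            "age_copy": age,
        })
        with pytest.raises(ValueError, match="age"):
            fit_glm_voxelwise(rng.standard_normal((n, 3, 3, 3)), design)

    def test_covariate_effect_does_not_inflate_group_t(self, rng):
        # outcome driven purely by a covariate; the group t should exceed
        # the one-tailed threshold at about its nominal rate
        n = 40
        cov = rng.standard_normal(n)
        design = pd.DataFrame({
            "intercept": np.ones(n),
            "group": np.r_[np.ones(20), np.zeros(20)],
            "cov": cov - cov.mean(),
        })
        shape = (16, 16, 10)
        stack = 0.8 * cov[:, None, None, None] + rng.standard_normal((n, *shape))
        tmap, _, df = fit_glm_voxelwise(stack, design)
        p = 0.05
        t_crit = scipy.stats.t.ppf(1 - p, df)
        rate = (tmap.data > t_crit).mean()
        se = np.sqrt(p * (1 - p) / np.prod(shape))
        assert abs(rate - p) < 4 * se

    def test_residuals_returned_for_smoothness(self, rng):
        stack = rng.standard_normal((8, 4, 4, 3))
        _, resid, _ = fit_glm_voxelwise(stack, _group_design(4, 4))
        assert resid.shape == stack.shape
        # residuals sum to zero over subjects at each voxel (intercept)
        np.testing.assert_allclose(resid.sum(axis=0), 0.0, atol=1e-10)


class TestBuildDesign:
    def test_basic_columns_and_centering(self):
        clin = pd.DataFrame({
            "group": ["patient", "control", "patient", "control"],
            "age": [30.0, 40.0, 50.0, 40.0],
            "sex": [0, 1, 0, 1],
            "mean_fd": [0.1, 0.2, 0.1, 0.2],
            "education_years": [12, 14, 12, 14],
            "gmv": [600, 620, 590, 610],
        })
        design = build_design(clin)
        assert list(design.columns)[:2] == ["intercept", "group"]
        assert design["group"].tolist() == [1.0, 0.0, 1.0, 0.0]
        assert design["age"].mean() == pytest.approx(0.0)

    def test_missing_covariate_skipped(self):
        clin = pd.DataFrame({"group": ["patient", "control"], "age": [30.0, 40.0]})
        design = build_design(clin, covariates=("age", "gmv"))
        assert "gmv" not in design.columns and "age" in design.columns


class TestThresholdAndCluster:
    def _tmap(self, data):
        data = np.asarray(data, float)
        return ScalarMap(data, default_affine(data.shape, 3.0))

    def test_zero_map_has_no_clusters(self):
        assert threshold_and_cluster(self._tmap(np.zeros((6, 6, 6))), df=20) == []

    def test_five_voxel_blob_single_cluster(self):
        data = np.zeros((8, 8, 8))
        blob = [(2, 2, 2), (3, 2, 2), (4, 2, 2), (4, 3, 2), (4, 3, 3)]
        for ijk in blob:
            data[ijk] = 10.0
        clusters = threshold_and_cluster(self._tmap(data), df=20)
        assert len(clusters) == 1
        assert clusters[0].extent_voxels == 5
        assert clusters[0].sign == 1
        assert clusters[0].peak_t == 10.0

    def test_corner_touching_blobs_depend_on_connectivity(self):
        data = np.zeros((8, 8, 8))
        data[2, 2, 2] = data[3, 3, 3] = 8.0  # touch only at a corner
        c26 = threshold_and_cluster(self._tmap(data), df=20, connectivity=26)
        c6 = threshold_and_cluster(self._tmap(data), df=20, connectivity=6)
        assert len(c26) == 1 and c26[0].extent_voxels == 2
        assert len(c6) == 2

    def test_signs_kept_separately(self):
        data = np.zeros((8, 8, 8))
        data[1, 1, 1] = 9.0
        data[5, 5, 5] = -9.0
        clusters = threshold_and_cluster(self._tmap(data), df=15)
        assert sorted(c.sign for c in clusters) == [-1, 1]

    def test_peak_mni_consistent_with_affine(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 9.0  # grid centre -> world origin
        cl = threshold_and_cluster(self._tmap(data), df=15)[0]
        assert cl.peak_mni == (0.0, 0.0, 0.0)


class TestSmoothness:
    def test_recovers_applied_fwhm_within_15pct(self, rng):
        # white noise smoothed with a 6 mm kernel on a 2 mm grid
        fwhm_mm, voxel = 6.0, 2.0
        sigma = fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / voxel
        stack = np.stack([
            scipy.ndimage.gaussian_filter(rng.standard_normal((40, 40, 30)), sigma, mode="wrap")
            for _ in range(8)
        ])
        est = estimate_smoothness(stack, np.ones((40, 40, 30), bool), voxel)
        np.testing.assert_allclose(est["fwhm_mm"], fwhm_mm, rtol=0.15)

    def test_unsmoothed_noise_fwhm_near_voxel_size(self, rng):
        voxel = 3.0
        stack = rng.standard_normal((8, 20, 20, 16))
        est = estimate_smoothness(stack, np.ones((20, 20, 16), bool), voxel)
        np.testing.assert_allclose(est["fwhm_mm"], voxel, rtol=0.25)

    def test_single_residual_map_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_smoothness(rng.standard_normal((1, 8, 8, 8)), np.ones((8, 8, 8), bool), 3.0)

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError):
            estimate_smoothness(np.ones((4, 8, 8, 8)), np.ones((8, 8, 8), bool), 3.0)


class TestGrf:
    SMOOTH = {"resels": 100.0, "n_voxels": 10000}

    def test_extent_zero_is_p_one(self):
        assert grf_cluster_p(0, self.SMOOTH, df=30) == 1.0

    def test_monotone_nonincreasing_in_extent(self):
        ps = [grf_cluster_p(k, self.SMOOTH, df=30) for k in (1, 5, 20, 100, 500)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert ps[-1] < 0.01  # huge clusters are significant

    def test_probability_bounds(self):
        for k in (1, 10, 1000):
            assert 0.0 <= grf_cluster_p(k, self.SMOOTH, df=30) <= 1.0


class TestPermutation:
    def test_extent_zero_gets_p_one_and_monotonicity(self, rng):
        n = 16
        stack = rng.standard_normal((n, 10, 10, 8))
        design = _group_design(8, 8)
        mask = np.ones((10, 10, 8), bool)
        tmap, _, df = fit_glm_voxelwise(stack, design, mask=mask)
        null = permutation_max_cluster_null(
            stack, design, "group", mask, df, voxel_p=0.05,
            n_permutations=200, rng=np.random.default_rng(0),
        )
        assert null.shape == (200,)
        # p for growing extents computed from the same null must not increase
        ps = [(1 + (null >= k).sum()) / 201 for k in (1, 3, 10, 50)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_familywise_error_controlled_on_null_maps(self, rng):
        # 40 null datasets; FWE at alpha = 0.05 stays inside the binomial band
        alpha, reps = 0.05, 40
        design = _group_design(8, 8)
        mask = np.ones((12, 12, 8), bool)
        false_pos = 0
        for rep in range(reps):
            stack = null_map_stack(16, (12, 12, 8), 2.0, rng)
            tmap, _, df = fit_glm_voxelwise(stack, design, mask=mask)
            clusters = threshold_and_cluster(tmap, df, voxel_p=0.01)
            if not clusters:
                continue
            clusters, sig = cluster_pvalues(
                clusters, method="permutation", cluster_alpha=alpha,
                stack=stack, design=design, mask=mask, df=df, voxel_p=0.01,
                n_permutations=250, rng=rng,
            )
            if sig:
                false_pos += 1
        lo, hi = scipy.stats.binom.interval(0.95, reps, alpha)
        assert lo <= false_pos <= hi + 1  # one count of slack on a 40-rep MC

    def test_zero_permutations_rejected(self, rng):
        stack = rng.standard_normal((8, 9, 9, 9))
        with pytest.raises(ValueError):
            permutation_max_cluster_null(
                stack, _group_design(4, 4), "group", np.ones((9, 9, 9), bool),
                df=6, n_permutations=0,
            )


class TestGroupAnalysis:
    def test_single_group_refused(self, rng):
        maps = [ScalarMap(rng.standard_normal((9, 9, 9)), np.eye(4)) for _ in range(6)]
        clin = pd.DataFrame({"group": ["control"] * 6})
        with pytest.raises(ValueError, match="both groups"):
            group_difference_analysis(maps, clin, covariates=())

    def test_injected_effect_recovered(self, rng):
        # strong focal group effect on otherwise-null maps
        shape = (14, 14, 10)
        effect = np.zeros(shape)
        effect[4:9, 4:9, 3:7] = 1.0
        n_a = n_b = 10
        maps = []
        for i in range(n_a + n_b):
            base = null_map_stack(1, shape, 2.0, rng)[0]
            if i < n_a:
                base = base + 2.0 * effect
            maps.append(ScalarMap(base, default_affine(shape, 3.0)))
        clin = pd.DataFrame({"group": ["patient"] * n_a + ["control"] * n_b})
        res = group_difference_analysis(
            maps, clin, covariates=(), n_permutations=300, rng=np.random.default_rng(5)
        )
        assert dice_coefficient(res["significant_mask"], effect > 0) >= 0.5
        assert all(cl.sign == 1 for cl in res["significant"])


class TestDice:
    def test_identical_masks(self):
        m = np.zeros((4, 4, 4), bool)
        m[1:3] = True
        assert dice_coefficient(m, m) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros((4, 4, 4), bool)
        a[0], b[3] = True, True
        assert dice_coefficient(a, b) == 0.0

    def test_empty_masks(self):
        z = np.zeros((3, 3, 3), bool)
        assert dice_coefficient(z, z) == 0.0
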