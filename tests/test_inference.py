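"""Voxel-wise GLM, FWE correction and cluster-extraction tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gfcmap import (
    VoxelwiseGroupGLM,
    build_design,
    build_gray_mask,
    extract_clusters,
    fit_voxelwise_glm,
    fwe_correct,
)
from gfcmap.inference import StatMap, FweResult


def two_group_design(n1, n2):
    group = np.r_[np.ones(n1), np.zeros(n2)]
    return np.column_stack([np.ones(n1 + n2), group])


class TestVoxelwiseGlm:
    def test_matches_pooled_two_sample_t(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=15), rng.normal(size=18)
        Y = np.r_[a, b][:, None]
        stat = fit_voxelwise_glm(Y, two_group_design(15, 18))
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert stat.t[0] == pytest.approx(ref.statistic, abs=1e-10)
        assert stat.p[0] == pytest.approx(ref.pvalue, abs=1e-10)
        assert stat.dof == 31

    def test_covariate_adjustment_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        n = 30
        group = np.r_[np.ones(15), np.zeros(15)]
        age = rng.normal(size=n)
        y = 0.4 * group + 0.2 * age + rng.normal(size=n)
        X = np.column_stack([np.ones(n), group, age - age.mean()])
        stat = fit_voxelwise_glm(y[:, None], X)
        fit = sm.OLS(y, X).fit()
        assert stat.t[0] == pytest.approx(fit.tvalues[1], abs=1e-10)

    def test_duplicated_group_column_raises_rank_error(self):
        X = two_group_design(5, 5)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="rank deficient"):
            fit_voxelwise_glm(np.random.default_rng(2).normal(size=(10, 3)), X)

    def test_identical_maps_give_zero_t(self):
        Y = np.ones((12, 5)) * 3.7
        stat = fit_voxelwise_glm(Y, two_group_design(6, 6))
        assert np.all(stat.t == 0)

    def test_constant_shift_leaves_t_unchanged(self):
        rng = np.random.default_rng(3)
        Y = rng.normal(size=(20, 8))
        X = two_group_design(10, 10)
        t0 = fit_voxelwise_glm(Y, X).t
        t1 = fit_voxelwise_glm(Y + 100.0, X).t
        assert np.allclose(t0, t1, atol=1e-9)

    def test_subject_permutation_invariance(self):
        rng = np.random.default_rng(4)
        Y = rng.normal(size=(16, 6))
        X = two_group_design(8, 8)
        perm = rng.permutation(16)
        t0 = fit_voxelwise_glm(Y, X).t
        t1 = fit_voxelwise_glm(Y[perm], X[perm]).t
        assert np.allclose(t0, t1, atol=1e-10)

    def test_group_swap_flips_t_sign(self):
        rng = np.random.default_rng(5)
        Y = rng.normal(size=(14, 4))
        X = two_group_design(7, 7)
        Xswap = X.copy()
        Xswap[:, 1] = 1 - Xswap[:, 1]
        assert np.allclose(
            fit_voxelwise_glm(Y, X).t, -fit_voxelwise_glm(Y, Xswap).t, atol=1e-10
        )


class TestBuildDesign:
    def _subjects(self, n=10):
        rng = np.random.default_rng(6)
        return pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n)],
                "group": ["patient"] * (n // 2) + ["control"] * (n - n // 2),
                "age": rng.normal(21, 2, n),
                "sex": rng.integers(0, 2, n),
                "education": rng.normal(14, 2, n),
                "mean_fd": rng.random(n) * 0.1,
            }
        )

    def test_columns_and_centering(self):
        X, names = build_design(self._subjects())
        assert names == ["intercept", "group", "age", "sex", "education", "mean_fd"]
        assert np.allclose(X[:, 2].mean(), 0, atol=1e-12)  # age centered
        assert set(np.unique(X[:, 3])) <= {0.0, 1.0}  # sex indicator

    def test_single_group_rejected(self):
        df = self._subjects()
        df["group"] = "patient"
        with pytest.raises(ValueError, match="both"):
            build_design(df)

    def test_missing_covariate_rejected(self):
        with pytest.raises(ValueError, match="mean_fd"):
            build_design(self._subjects().drop(columns="mean_fd"))


class TestFweCorrect:
    def _stat_and_data(self, seed=0, n1=10, n2=10, V=30):
        rng = np.random.default_rng(seed)
        Y = rng.normal(size=(n1 + n2, V))
        X = two_group_design(n1, n2)
        return fit_voxelwise_glm(Y, X), Y, X

    def test_bonferroni_threshold_is_alpha_over_v(self):
        stat, Y, X = self._stat_and_data(V=10)
        fwe = fwe_correct(stat, Y, X, method="bonferroni", alpha=0.05)
        assert np.array_equal(fwe.significant, stat.p < 0.005)
        # |t| threshold reproduces the same set
        assert np.array_equal(fwe.significant, np.abs(stat.t) > fwe.threshold)

    def test_maxt_quantile_boundary_alpha_near_one(self):
        stat, Y, X = self._stat_and_data(1)
        n_perm = 128
        fwe = fwe_correct(
            stat, Y, X, alpha=1 - 1 / n_perm, n_permutations=n_perm, seed=3
        )
        assert fwe.threshold == fwe.max_t_null.min()

    def test_maxt_threshold_at_least_uncorrected(self):
        stat, Y, X = self._stat_and_data(2)
        fwe = fwe_correct(stat, Y, X, alpha=0.05, n_permutations=200, seed=4)
        single_voxel = stats.t.isf(0.025, stat.dof)
        assert fwe.threshold >= single_voxel

    def test_deterministic_given_seed(self):
        stat, Y, X = self._stat_and_data(3)
        a = fwe_correct(stat, Y, X, n_permutations=150, seed=9)
        b = fwe_correct(stat, Y, X, n_permutations=150, seed=9)
        assert a.threshold == b.threshold
        assert np.array_equal(a.max_t_null, b.max_t_null)

    def test_identity_permutation_included(self):
        stat, Y, X = self._stat_and_data(4)
        fwe = fwe_correct(stat, Y, X, n_permutations=100, seed=5)
        assert fwe.max_t_null[0] == pytest.approx(np.abs(stat.t).max(), abs=1e-10)

    def test_too_few_permutations_rejected(self):
        stat, Y, X = self._stat_and_data(5)
        with pytest.raises(ValueError, match="100"):
            fwe_correct(stat, Y, X, n_permutations=50)

    def test_invalid_alpha_rejected(self):
        stat, Y, X = self._stat_and_data(6)
        with pytest.raises(ValueError, match="alpha"):
            fwe_correct(stat, Y, X, alpha=1.5, n_permutations=100)


class TestExtractClusters:
    def _mask(self, shape=(4, 4, 4)):
        return build_gray_mask(np.full(shape, 0.9), 0.2, affine=np.eye(4))

    def _stat(self, mask, t_by_voxel):
        t = np.zeros(len(mask))
        for vox, val in t_by_voxel.items():
            idx = mask.member_voxels.tolist().index(list(vox))
            t[idx] = val
        p = np.full(len(mask), 1.0)
        return StatMap(t=t, p=p, dof=10)

    def _fwe(self, stat, threshold):
        return FweResult(
            method="bonferroni", alpha=0.05, threshold=threshold,
            significant=np.abs(stat.t) > threshold,
        )

    def test_singleton_cluster(self):
        mask = self._mask()
        stat = self._stat(mask, {(1, 2, 3): 6.0})
        clusters = extract_clusters(stat, self._fwe(stat, 5.0), mask)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.n_voxels == 1 and c.peak_t == 6.0
        assert c.peak_mni == (1.0, 2.0, 3.0)
        assert c.direction == "patients>controls"

    def test_corner_touch_is_one_cluster_under_26_connectivity(self):
        mask = self._mask()
        stat = self._stat(mask, {(0, 0, 0): 6.0, (1, 1, 1): 5.5})
        c26 = extract_clusters(stat, self._fwe(stat, 5.0), mask, connectivity=26)
        c6 = extract_clusters(stat, self._fwe(stat, 5.0), mask, connectivity=6)
        assert len(c26) == 1 and c26[0].n_voxels == 2
        assert len(c6) == 2

    def test_signs_split_and_sorting(self):
        mask = self._mask()
        stat = self._stat(mask, {(0, 0, 0): 6.0, (0, 0, 1): -8.0, (3, 3, 3): 7.0})
        clusters = extract_clusters(stat, self._fwe(stat, 5.0), mask)
        # negative peak is largest in magnitude -> first
        assert [c.peak_t for c in clusters] == [-8.0, 7.0, 6.0]
        assert clusters[0].direction == "patients<controls"
        assert [c.cluster_id for c in clusters] == ["cluster1", "cluster2", "cluster3"]

    def test_affine_maps_peak_to_mni(self):
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
        affine[:3, 3] = [-24, -30, -18]
        mask = build_gray_mask(np.full((4, 4, 4), 0.9), 0.2, affine=affine)
        stat = self._stat(mask, {(2, 1, 3): 9.0})
        c = extract_clusters(stat, self._fwe(stat, 5.0), mask)[0]
        assert c.peak_mni == (-18.0, -27.0, -9.0)

    def test_empty_significant_set(self):
        mask = self._mask()
        stat = self._stat(mask, {})
        assert extract_clusters(stat, self._fwe(stat, 5.0), mask) == []


class TestVoxelwiseGroupGLMEstimator:
    def test_fit_exposes_sklearn_style_attributes(self):
        rng = np.random.default_rng(7)
        Y = rng.normal(size=(20, 12))
        y = np.r_[np.ones(10), np.zeros(10)]
        est = VoxelwiseGroupGLM(n_permutations=100, random_state=0)
        est.fit(Y, y)
        assert est.t_.shape == (12,)
        assert est.dof_ == 18
        assert est.significant_.dtype == bool
        assert est.get_params()["n_permutations"] == 100
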