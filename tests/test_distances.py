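"""Shrinkage covariance, Mahalanobis distances and robust subsampled
scores."""

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import mahalanobis as scipy_mahalanobis

from tractnorm.cohort import Group, LEFT_TRACTS, TRACTS
from tractnorm.distances import (
    DistanceSet, compute_distance_set, draw_subsets, ledoit_wolf_batch,
    mahalanobis, robust_mahalanobis, robust_zscore, shrinkage_covariance,
)
from tractnorm.errors import DegenerateDataError, TooFewControlsError
from tractnorm.synthetic import GeneratorConfig, generate_cohort
from tractnorm.covariates import residualize


class TestMahalanobis:
    def test_zero_at_the_centroid(self):
        mu = np.array([0.1, 0.2, 0.3])
        C = np.diag([1.0, 2.0, 3.0])
        assert mahalanobis(mu, mu, C) == 0.0

    def test_univariate_reduction(self):
        assert mahalanobis([3.0], [1.0], [[4.0]]) == pytest.approx(1.0)

    def test_hand_inverted_two_by_two(self):
        # (1,1)' [[1,.5],[.5,1]]^{-1} (1,1) = 4/3
        d = mahalanobis([1.0, 1.0], [0.0, 0.0],
                        np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert d == pytest.approx(np.sqrt(4.0 / 3.0), abs=1e-12)

    def test_matches_scipy_on_random_spd(self, rng):
        A = rng.normal(size=(6, 4))
        C = A.T @ A + np.eye(4)
        x, mu = rng.normal(size=4), rng.normal(size=4)
        assert mahalanobis(x, mu, C) == pytest.approx(
            scipy_mahalanobis(x, mu, np.linalg.inv(C)), abs=1e-10)

    def test_scaling_the_deviation_scales_the_distance(self, rng):
        C = np.eye(3) + 0.3
        mu = np.zeros(3)
        x = rng.normal(size=3)
        lam = 2.7
        assert mahalanobis(lam * x, mu, C) == pytest.approx(
            lam * mahalanobis(x, mu, C), rel=1e-12)

    def test_non_spd_covariance_rejected(self):
        with pytest.raises(DegenerateDataError):
            mahalanobis([1.0, 1.0], [0.0, 0.0],
                        np.array([[1.0, 2.0], [2.0, 1.0]]))


class TestShrinkageCovariance:
    def test_matches_sklearn_ledoit_wolf(self, rng):
        """The intensity and matrix must equal an independently coded
        Ledoit-Wolf estimator to near machine precision."""
        from sklearn.covariance import ledoit_wolf
        X = rng.normal(size=(6, 3)) @ np.diag([1.0, 2.0, 0.5])
        est = shrinkage_covariance(X)
        sk_cov, sk_shrinkage = ledoit_wolf(X)
        assert est.shrinkage_intensity == pytest.approx(sk_shrinkage,
                                                        abs=1e-10)
        # sklearn uses the biased (n) normalisation; ours carries the
        # n/(n-1) correction that makes p=1 reduce to the unbiased variance
        assert est.matrix * (5 / 6) == pytest.approx(sk_cov, abs=1e-10)

    def test_large_sample_consistency_for_diagonal_truth(self, rng):
        truth = np.diag([1.0, 2.0, 3.0, 4.0])
        X = rng.multivariate_normal(np.zeros(4), truth, size=10_000)
        est = shrinkage_covariance(X)
        assert est.shrinkage_intensity < 0.05
        assert np.abs(est.matrix - truth).max() < 0.02 * truth.max()

    def test_always_spd_at_small_n(self):
        """n=24, p=5 Gaussian draws: the shrunk matrix must be SPD in all
        of 1,000 seeded repeats."""
        rng = np.random.default_rng(99)
        X = rng.normal(size=(1000, 24, 5))
        covs, intensity = ledoit_wolf_batch(X)
        assert np.linalg.eigvalsh(covs).min() > 0
        assert np.all((intensity >= 0) & (intensity <= 1))

    def test_constant_column_still_spd(self, rng):
        X = rng.normal(size=(20, 3))
        X[:, 1] = 0.7
        est = shrinkage_covariance(X)
        assert np.linalg.eigvalsh(est.matrix).min() > 0
        assert 0 < est.shrinkage_intensity <= 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            shrinkage_covariance(np.ones((2, 3)))


class TestRobustZscore:
    def test_value_at_reference_centre_scores_near_zero(self, rng):
        ref = rng.normal(10.0, 2.0, size=200)
        z = robust_zscore(float(ref.mean()), ref, seed=0)
        assert abs(z) < 0.05

    def test_zero_variance_reference_rejected(self):
        with pytest.raises(DegenerateDataError):
            robust_zscore(1.0, np.full(30, 5.0), seed=0)

    def test_median_of_subsamples_tracks_full_sample_z(self, rng):
        ref = rng.normal(0.0, 1.0, size=10_000)
        value = 1.3
        full_z = (value - ref.mean()) / ref.std(ddof=1)
        z = robust_zscore(value, ref, n_subsample=24, n_reps=2000, seed=1)
        assert z == pytest.approx(full_z, abs=0.05)

    def test_seeded_determinism(self, rng):
        ref = rng.normal(size=100)
        assert robust_zscore(0.5, ref, seed=42) == \
            robust_zscore(0.5, ref, seed=42)


class TestRobustMahalanobis:
    def test_centroid_scores_below_typical_reference_point(self, rng):
        ref = rng.multivariate_normal(np.zeros(3), np.eye(3) + 0.4,
                                      size=60)
        d_centre = robust_mahalanobis(ref.mean(axis=0), ref, seed=0)
        d_typical = np.median([
            robust_mahalanobis(row, np.delete(ref, i, axis=0), seed=0)
            for i, row in enumerate(ref[:10])])
        assert d_centre < d_typical

    def test_univariate_case_matches_absolute_zscore(self, rng):
        """p=1 with the same subsample protocol: DM == |z| up to the
        biased-vs-unbiased SD convention, well within 0.05."""
        ref = rng.normal(0.3, 0.05, size=28)
        value = 0.38
        z = robust_zscore(value, ref, n_subsample=24, n_reps=1000, seed=3)
        d = robust_mahalanobis(np.array([value]), ref[:, None],
                               n_subsample=24, n_reps=1000, seed=3)
        assert d == pytest.approx(abs(z), abs=0.05)

    def test_affine_invariance_with_sample_covariance(self, rng):
        ref = rng.multivariate_normal(np.zeros(3), np.eye(3) + 0.2,
                                      size=80)
        x = rng.normal(size=3)
        A = rng.normal(size=(3, 3)) + np.eye(3) * 2
        b = rng.normal(size=3)
        d0 = robust_mahalanobis(x, ref, n_subsample=40, n_reps=200, seed=5,
                                estimator="sample")
        d1 = robust_mahalanobis(A @ x + b, ref @ A.T + b, n_subsample=40,
                                n_reps=200, seed=5, estimator="sample")
        assert d1 == pytest.approx(d0, abs=1e-6)

    def test_subsample_size_preconditions(self, rng):
        ref = rng.normal(size=(20, 5))
        with pytest.raises(ValueError):
            robust_mahalanobis(np.zeros(5), ref, n_subsample=6)  # < p+2
        with pytest.raises(ValueError):
            robust_mahalanobis(np.zeros(5), ref, n_subsample=20)  # = m


class TestDrawSubsets:
    def test_subsets_are_valid_and_uniform_ish(self):
        rng = np.random.default_rng(0)
        idx = draw_subsets(rng, 4000, 10, 4)
        assert idx.shape == (4000, 4)
        for row in idx[:50]:
            assert len(set(row)) == 4
        counts = np.bincount(idx.ravel(), minlength=10)
        assert counts.min() > 0.9 * counts.mean()


class TestComputeDistanceSet:
    def test_deterministic_and_order_invariant(self, default_cohort,
                                               default_residuals):
        subjects, _ = default_cohort
        a = compute_distance_set(default_residuals, subjects, n_reps=50,
                                 seed=3)
        b = compute_distance_set(default_residuals, subjects, n_reps=50,
                                 seed=3)
        assert a.frame.equals(b.frame)
        # per-subject streams: shuffling subject order cannot change scores
        shuffled = list(subjects)[::-1]
        c = compute_distance_set(default_residuals.iloc[::-1], shuffled,
                                 n_reps=50, seed=3)
        assert c.frame.sort_index().equals(a.frame.sort_index())

    def test_two_control_distances_per_control(self, default_cohort,
                                               default_distances):
        subjects, _ = default_cohort
        ctrl_dist = default_distances.control_distances(subjects)
        assert ctrl_dist.shape == (56,)    # 2 x 28 controls
        assert (ctrl_dist > 0).all()

    def test_patient_laterality_relabelling(self, default_cohort,
                                            default_distances):
        subjects, _ = default_cohort
        frame = default_distances.frame
        for s in subjects:
            row = frame.loc[s.subject_id]
            if s.group is Group.LEFT_TLE:
                assert row["md_ipsi"] == row["md_left"]
                assert row["md_contra"] == row["md_right"]
            elif s.group is Group.RIGHT_TLE:
                assert row["md_ipsi"] == row["md_right"]
            else:
                assert np.isnan(row["md_ipsi"])

    def test_too_few_controls_rejected(self, default_residuals,
                                       default_cohort):
        subjects, _ = default_cohort
        few = [s for s in subjects if s.is_patient] + \
            [s for s in subjects if not s.is_patient][:10]
        resid = default_residuals.loc[[s.subject_id for s in few]]
        with pytest.raises(TooFewControlsError):
            compute_distance_set(resid, few)

    def test_null_cohort_patient_and_control_distances_indistinguishable(
            self, null_cohort):
        subjects, fa = null_cohort
        resid, _ = residualize(fa, subjects)
        ok = 0
        for seed in range(10):
            ds = compute_distance_set(resid, subjects, n_reps=100,
                                      seed=seed)
            md_ctrl = ds.control_distances(subjects)
            pat = [s.subject_id for s in subjects if s.is_patient]
            md_pat = np.concatenate([
                ds.frame.loc[pat, "md_left"], ds.frame.loc[pat, "md_right"]])
            p = stats.mannwhitneyu(md_ctrl, md_pat).pvalue
            ok += p > 0.01
        assert ok >= 9
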