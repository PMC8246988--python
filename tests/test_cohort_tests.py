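"""Chi-squared, t-tests, outcome comparisons and normality checks."""

import numpy as np
import pytest
from scipy import stats

from tractnorm.cohort import Group, Outcome
from tractnorm.cohort_tests import (
    _lilliefors_statistic, demographic_tests, lilliefors, mardia,
    outcome_comparison, two_sample_t, yates_chi2,
)
from tractnorm.covariates import residualize
from tractnorm.distances import compute_distance_set
from tractnorm.errors import DegenerateDataError
from tractnorm.synthetic import GeneratorConfig, generate_cohort


class TestYatesChi2:
    def test_balanced_table_is_exactly_null(self):
        res = yates_chi2([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_invariant_under_transpose_and_swaps(self, rng):
        table = np.array([[16, 12], [17, 16]])
        p0 = yates_chi2(table).p_value
        for variant in (table.T, table[::-1], table[:, ::-1]):
            assert yates_chi2(variant).p_value == pytest.approx(p0,
                                                                abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateDataError):
            yates_chi2([[0, 0], [5, 3]])


class TestTwoSampleT:
    def test_identical_groups_are_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        res = two_sample_t(x, x)
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_one_tailed_p_is_half_two_tailed_in_observed_direction(
            self, rng):
        x = rng.normal(1.0, 1.0, 12)
        y = rng.normal(0.0, 1.0, 15)
        if x.mean() < y.mean():
            x, y = y, x
        two = two_sample_t(x, y, tails="two")
        one = two_sample_t(x, y, tails="one", direction="greater")
        assert one.p_value == pytest.approx(two.p_value / 2, abs=1e-12)

    def test_matches_hand_formula_on_fixed_fixture(self):
        x = np.array([0.1, 0.4, 0.2, 0.5, 0.3])
        y = np.array([0.6, 0.8, 0.7, 1.0, 0.9])
        nx, ny = 5, 5
        sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) \
            / (nx + ny - 2)
        t_hand = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / nx + 1 / ny))
        res = two_sample_t(x, y)
        assert res.statistic == pytest.approx(t_hand, abs=1e-12)
        assert res.df == nx + ny - 2
        assert res.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_hand), nx + ny - 2), abs=1e-12)


class TestLilliefors:
    def test_statistic_matches_sup_distance_oracle(self):
        """Direct oracle: max of the two one-sided sup gaps between the
        ECDF and the fitted normal CDF, evaluated pointwise."""
        x = np.array([1.0, 1.2, 1.9, 2.4, 3.1, 5.0])
        n = x.size
        z = (np.sort(x) - x.mean()) / x.std(ddof=1)
        cdf = stats.norm.cdf(z)
        d_oracle = max(max((i + 1) / n - cdf[i] for i in range(n)),
                       max(cdf[i] - i / n for i in range(n)))
        res = lilliefors(x, n_mc=500, seed=0)
        assert res.statistic == pytest.approx(d_oracle, abs=1e-12)

    def test_statistic_agrees_with_statsmodels(self, rng):
        from statsmodels.stats.diagnostic import lilliefors as sm_lf
        x = rng.normal(size=28)
        d_sm, _ = sm_lf(x, dist="norm")
        assert lilliefors(x, n_mc=200, seed=0).statistic == pytest.approx(
            d_sm, abs=1e-10)

    def test_monte_carlo_null_calibration(self):
        """Rejection rate at alpha=0.05 for normal samples of n=28 must be
        ~5%: compare 2,000 fresh statistics to the MC critical value."""
        rng = np.random.default_rng(7)
        null_stats = _lilliefors_statistic(
            np.sort(rng.standard_normal((20_000, 28)), axis=1))
        crit = np.quantile(null_stats, 0.95)
        fresh = _lilliefors_statistic(
            np.sort(rng.standard_normal((2000, 28)), axis=1))
        rate = np.mean(fresh > crit)
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_outlier_increases_the_statistic(self, rng):
        x = rng.normal(size=30)
        x_out = x.copy()
        x_out[0] += 10.0
        assert lilliefors(x_out, n_mc=200, seed=0).statistic > \
            lilliefors(x, n_mc=200, seed=0).statistic

    def test_p_reproducible_for_fixed_seed(self, rng):
        x = rng.normal(size=25)
        assert lilliefors(x, seed=3).p_value == lilliefors(x, seed=3).p_value

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            lilliefors(np.full(10, 3.0))


class TestMardia:
    def test_univariate_reduction_to_moment_formulas(self, rng):
        x = rng.normal(size=(40, 1))
        skew_res, kurt_res = mardia(x)
        xc = x[:, 0] - x.mean()
        m2 = (xc ** 2).mean()
        b1_classic = ((xc ** 3).mean() / m2 ** 1.5) ** 2
        b2_classic = (xc ** 4).mean() / m2 ** 2
        assert skew_res.statistic == pytest.approx(
            40 * b1_classic / 6, abs=1e-10)
        kurt_z = (b2_classic - 3.0) / np.sqrt(24.0 / 40)
        assert kurt_res.statistic == pytest.approx(kurt_z, abs=1e-10)

    def test_matches_double_sum_oracle_on_fixed_fixture(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0], [3.0, 5.0], [4.0, 3.0],
                      [0.5, 2.5]])
        n, p = X.shape
        Xc = X - X.mean(axis=0)
        S_inv = np.linalg.inv(Xc.T @ Xc / n)
        b1 = sum((Xc[i] @ S_inv @ Xc[j]) ** 3
                 for i in range(n) for j in range(n)) / n ** 2
        b2 = sum((Xc[i] @ S_inv @ Xc[i]) ** 2 for i in range(n)) / n
        skew_res, kurt_res = mardia(X)
        assert skew_res.statistic == pytest.approx(n * b1 / 6, abs=1e-10)
        assert kurt_res.statistic == pytest.approx(
            (b2 - p * (p + 2)) / np.sqrt(8 * p * (p + 2) / n), abs=1e-10)

    def test_affine_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        A = rng.normal(size=(3, 3)) + 2 * np.eye(3)
        b = rng.normal(size=3)
        s0, k0 = mardia(X)
        s1, k1 = mardia(X @ A.T + b)
        assert s1.statistic == pytest.approx(s0.statistic, abs=1e-8)
        assert k1.statistic == pytest.approx(k0.statistic, abs=1e-8)

    def test_gaussian_data_rarely_rejected(self, rng):
        rejections = 0
        for _ in range(20):
            X = rng.multivariate_normal(np.zeros(5), np.eye(5) + 0.4, 28)
            s, k = mardia(X)
            rejections += (s.p_value < 0.01) + (k.p_value < 0.01)
        assert rejections <= 4


class TestOutcomeComparison:
    def test_contralateral_deficit_detected(self):
        """Patients with poor outcomes get an extra contralateral FA
        deficit; the contralateral distance test must pick it up in most
        replicates."""
        cfg = GeneratorConfig(outcome_deficit_contra=0.04)
        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            subjects, fa = generate_cohort(cfg, seed=seed)
            resid, _ = residualize(fa, subjects)
            ds = compute_distance_set(resid, subjects, n_reps=100,
                                      seed=seed, include_controls=False)
            res = {(r.group, r.measure_id): r
                   for r in outcome_comparison(ds, subjects)}
            hits += res[("left_tle", "md_contra")].significant_corrected
        assert hits >= 0.8 * n_rep

    def test_shuffled_labels_control_false_positives(self, default_cohort,
                                                     default_distances):
        """Permutation null: corrected significance occurs at no more than
        the corrected alpha rate."""
        subjects, _ = default_cohort
        rng = np.random.default_rng(0)
        n_shuffles = 200
        per_shuffle_rates = []
        patients = [s for s in subjects if s.is_patient]
        for _ in range(n_shuffles):
            outcomes = [s.ilae_outcome for s in patients]
            rng.shuffle(outcomes)
            import dataclasses
            shuffled = [s for s in subjects if not s.is_patient] + [
                dataclasses.replace(s, ilae_outcome=o)
                for s, o in zip(patients, outcomes)]
            results = outcome_comparison(default_distances, shuffled)
            per_shuffle_rates.append(
                np.mean([r.significant_corrected for r in results]))
        # the 24 tests within one shuffle are correlated, so use a
        # cluster (per-shuffle) standard error around the corrected rate
        rate = np.mean(per_shuffle_rates)
        se = np.std(per_shuffle_rates, ddof=1) / np.sqrt(n_shuffles)
        assert rate <= 0.005 + 3 * max(se, 1e-4)

    def test_single_outcome_class_rejected(self, default_cohort,
                                           default_distances):
        import dataclasses
        subjects, _ = default_cohort
        forced = [dataclasses.replace(s, ilae_outcome=Outcome.ILAE1)
                  if s.is_patient else s for s in subjects]
        with pytest.raises(ValueError, match="outcome classes"):
            outcome_comparison(default_distances, forced)


class TestDemographicTests:
    def test_layout_of_the_demographics_report(self, default_cohort):
        subjects, _ = default_cohort
        results = demographic_tests(subjects)
        names = [(r.measure_id, r.group) for r in results]
        assert ("sex", "control vs left_tle") in names
        assert ("ilae_outcome", "left_tle vs right_tle") in names
        assert ("duration_years", "left_tle vs right_tle") in names
        assert all(0 <= r.p_value <= 1 for r in results)
        # balanced null generator: age should not differ between groups
        age_tests = [r for r in results if r.measure_id == "age_years"]
        assert all(r.p_value > 0.001 for r in age_tests)
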