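"""Auxiliary hypothesis tests: demographics, surgical outcome, normality.

Chi-squared tests on 2x2 demographic tables use the Yates continuity
correction; group comparisons of continuous demographics use two-sample
t-tests. Surgical-outcome comparisons are one-tailed two-sample t-tests of
each distance measure between seizure-free (ILAE 1) and not-seizure-free
(ILAE 2+) patients. Normality of the control residuals — the Mahalanobis
reference — is gated univariately by a Lilliefors test (Monte-Carlo null
for the estimated-parameter KS statistic) and multivariately by Mardia's
skewness and kurtosis tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TRACTS, Group, Outcome, SubjectRecord
from .distances import DistanceSet
from .errors import DegenerateDataError

ONE = "one"
TWO = "two"


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float
    p_value: float
    tails: str
    direction: str | None = None
    h: int | None = None
    significant_corrected: bool | None = None
    measure_id: str | None = None
    group: str | None = None


def yates_chi2(table) -> TestResult:
    """Pearson chi-squared on a 2x2 count table with Yates continuity
    correction (|O-E| reduced by 0.5, floored at 0), 1 df, two-tailed."""
    table = np.asarray(table)
    if table.shape != (2, 2) or (table < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero marginal in contingency table")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=True)
    return TestResult("yates_chi2", float(chi2), float(df), float(p), TWO)


def two_sample_t(x, y, tails: str = TWO, direction: str | None = None,
                 variance: str = "pooled") -> TestResult:
    """Two-sample t-test of mean(x) vs mean(y).

    ``direction`` (one-tailed only): ``"greater"``/``"less"`` hypothesises
    mean(x) >/< mean(y). Pooled variance by default; ``"welch"`` available.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if np.ptp(np.concatenate([x, y])) == 0:
        raise DegenerateDataError("zero variance in both samples")
    if variance not in ("pooled", "welch"):
        raise ValueError(f"unknown variance option {variance!r}")
    if tails == TWO:
        alternative = "two-sided"
    elif tails == ONE:
        if direction not in ("greater", "less"):
            raise ValueError("one-tailed test needs direction "
                             "'greater' or 'less'")
        alternative = direction
    else:
        raise ValueError(f"unknown tails {tails!r}")
    res = stats.ttest_ind(x, y, equal_var=(variance == "pooled"),
                          alternative=alternative)
    return TestResult("two_sample_t", float(res.statistic), float(res.df),
                      float(res.pvalue), tails, direction=direction)


def lilliefors(x, n_mc: int = 10_000, seed: int = 0) -> TestResult:
    """Lilliefors normality test: KS distance to a normal with estimated
    mean/SD, p by seeded Monte-Carlo simulation of the estimated-parameter
    null (not the standard KS table)."""
    x = np.asarray(x, float)
    n = x.size
    if n < 5:
        raise ValueError("need n >= 5")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance")
    d_obs = _lilliefors_statistic(np.sort(x)[None, :])[0]
    rng = np.random.default_rng(seed)
    sims = np.sort(rng.standard_normal((n_mc, n)), axis=1)
    d_null = _lilliefors_statistic(sims)
    p = (1.0 + np.count_nonzero(d_null >= d_obs)) / (n_mc + 1.0)
    return TestResult("lilliefors", float(d_obs), float("nan"), float(p), TWO)


def _lilliefors_statistic(sorted_rows: np.ndarray) -> np.ndarray:
    """Row-wise sup |ECDF - Phi((x - mean)/sd)| at both one-sided sup
    points; rows must be pre-sorted."""
    n = sorted_rows.shape[1]
    z = (sorted_rows - sorted_rows.mean(axis=1, keepdims=True)) \
        / sorted_rows.std(axis=1, ddof=1, keepdims=True)
    cdf = stats.norm.cdf(z)
    grid = np.arange(1, n + 1) / n
    d_plus = (grid[None, :] - cdf).max(axis=1)
    d_minus = (cdf - (np.arange(n) / n)[None, :]).max(axis=1)
    return np.maximum(d_plus, d_minus)


def mardia(X) -> tuple[TestResult, TestResult]:
    """Mardia's multivariate skewness and kurtosis tests.

    Uses the double-sum definitions with the n-denominator sample
    covariance: skewness statistic n*b1p/6 ~ chi2 with p(p+1)(p+2)/6 df;
    kurtosis z = (b2p - p(p+2)) / sqrt(8 p (p+2) / n), two-tailed normal.
    """
    X = np.asarray(X, float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (n, p)")
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1, got n={n}, p={p}")
    Xc = X - X.mean(axis=0)
    S = Xc.T @ Xc / n
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"singular covariance: {exc}") from exc
    G = Xc @ S_inv @ Xc.T
    b1 = float((G ** 3).mean())
    b2 = float((np.diag(G) ** 2).mean())
    skew_stat = n * b1 / 6.0
    skew_df = p * (p + 1) * (p + 2) / 6.0
    skew = TestResult("mardia_skewness", skew_stat, skew_df,
                      float(stats.chi2.sf(skew_stat, skew_df)), TWO)
    kurt_z = (b2 - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    kurt = TestResult("mardia_kurtosis", float(kurt_z), float("nan"),
                      float(2.0 * stats.norm.sf(abs(kurt_z))), TWO)
    return skew, kurt


# --------------------------------------------------------------------------
# Cohort-level reports
# --------------------------------------------------------------------------

def outcome_comparison(distances: DistanceSet,
                       subjects: Sequence[SubjectRecord],
                       alpha: float = 0.05,
                       variance: str = "pooled") -> list[TestResult]:
    """Per patient group, one-tailed t-tests of each measure between
    surgical-outcome classes.

    Hypotheses: not-seizure-free patients have *more negative* tract
    z-scores (h=10) and *larger* log Mahalanobis distances (h=2). The
    statistic is oriented seizure-free minus not-seizure-free.
    """
    frame = distances.frame
    results: list[TestResult] = []
    for group in (Group.LEFT_TLE, Group.RIGHT_TLE):
        members = [s for s in subjects if s.group is group]
        sf = [s.subject_id for s in members
              if s.ilae_outcome is Outcome.ILAE1]
        nsf = [s.subject_id for s in members
               if s.ilae_outcome is Outcome.ILAE2PLUS]
        if not sf or not nsf:
            raise ValueError(
                f"{group.value}: both outcome classes must be non-empty")
        for tract in TRACTS:
            col = f"z_{tract}"
            res = two_sample_t(frame.loc[sf, col], frame.loc[nsf, col],
                               tails=ONE, direction="greater",
                               variance=variance)
            res.measure_id = col
            res.group = group.value
            res.h = 10
            res.significant_corrected = res.p_value < alpha / res.h
            results.append(res)
        for measure in ("md_ipsi", "md_contra"):
            res = two_sample_t(np.log(frame.loc[sf, measure]),
                               np.log(frame.loc[nsf, measure]),
                               tails=ONE, direction="less",
                               variance=variance)
            res.measure_id = measure
            res.group = group.value
            res.h = 2
            res.significant_corrected = res.p_value < alpha / res.h
            results.append(res)
    return results


def demographic_tests(subjects: Sequence[SubjectRecord],
                      variance: str = "pooled") -> list[TestResult]:
    """Pairwise group comparisons of the demographic table: sex (and, for
    the patient pair, outcome and HS) by Yates chi-squared; age, onset and
    duration by two-tailed t-tests."""
    by_group = {g: [s for s in subjects if s.group is g] for g in Group}
    pairs = [(Group.CONTROL, Group.LEFT_TLE),
             (Group.CONTROL, Group.RIGHT_TLE),
             (Group.LEFT_TLE, Group.RIGHT_TLE)]
    results: list[TestResult] = []

    def _tag(res, name, a, b):
        res.measure_id = name
        res.group = f"{a.value} vs {b.value}"
        results.append(res)

    for a, b in pairs:
        ga, gb = by_group[a], by_group[b]
        if not ga or not gb:
            continue
        table = [[sum(s.sex.value == "F" for s in g),
                  sum(s.sex.value == "M" for s in g)] for g in (ga, gb)]
        _tag(yates_chi2(table), "sex", a, b)
        _tag(two_sample_t([s.age_years for s in ga],
                          [s.age_years for s in gb], variance=variance),
             "age_years", a, b)
    left, right = by_group[Group.LEFT_TLE], by_group[Group.RIGHT_TLE]
    if left and right:
        for attr in ("onset_age_years", "duration_years"):
            _tag(two_sample_t([getattr(s, attr) for s in left],
                              [getattr(s, attr) for s in right],
                              variance=variance),
                 attr, Group.LEFT_TLE, Group.RIGHT_TLE)
        for name, pred in (
                ("ilae_outcome",
                 lambda s: s.ilae_outcome is Outcome.ILAE1),
                ("hs_present", lambda s: bool(s.hs_present))):
            table = [[sum(pred(s) for s in g),
                      sum(not pred(s) for s in g)] for g in (left, right)]
            _tag(yates_chi2(table), name, Group.LEFT_TLE, Group.RIGHT_TLE)
    return results


def normality_report(control_residuals: pd.DataFrame, alpha: float = 0.05,
                     n_mc: int = 10_000, seed: int = 0) -> list[TestResult]:
    """Normality gating of the control reference: a Lilliefors test per
    tract (Bonferroni over 10) and Mardia skewness/kurtosis per hemisphere
    (the two 5-tract blocks entering the Mahalanobis distance)."""
    results = []
    for i, tract in enumerate(TRACTS):
        res = lilliefors(control_residuals[tract].to_numpy(), n_mc=n_mc,
                         seed=seed + i)
        res.measure_id = tract
        res.h = len(TRACTS)
        res.significant_corrected = res.p_value < alpha / res.h
        results.append(res)
    for side in ("L", "R"):
        cols = [t for t in TRACTS if t.endswith(f".{side}")]
        skew, kurt = mardia(control_residuals[cols].to_numpy())
        for res in (skew, kurt):
            res.measure_id = f"hemisphere_{side}"
            res.h = 2
            res.significant_corrected = res.p_value < alpha / res.h
            results.append(res)
    return results


def tests_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
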