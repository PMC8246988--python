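"""Subsample-consistency robustness of the duration correlations.

For a measure with a hypothesised direction, repeatedly draw a random
subsample of m patients (without replacement), recompute the one-tailed
Spearman test at the Bonferroni-corrected level alpha/h (the t threshold
uses n = m), and report kappa = the percentage of subsamples that come out
significant. A robust association sits near 100%, a robust null near 0%;
intermediate kappa flags results that flip with the sample drawn. Distances
are *not* recomputed per subsample — only the patients entering the
correlation vary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .associations import H_MULTIVARIATE, H_UNIVARIATE, NEGATIVE, POSITIVE
from .cohort import TRACTS, Group, SubjectRecord
from .distances import DistanceSet, draw_subsets

logger = logging.getLogger(__name__)


@dataclass
class ConsistencyResult:
    measure_id: str
    group: str
    subsample_size: int
    n_reps: int
    kappa: float          # percent of subsamples significant, in [0, 100]
    alpha: float
    h: int
    direction: str
    rng_seed: int
    n_discarded: int = 0


def _rank_rows(a: np.ndarray) -> np.ndarray:
    return stats.rankdata(a, axis=1, method="average")


def consistency(values: Sequence[float], durations: Sequence[float],
                m: int = 30, n_reps: int = 1000, alpha: float = 0.05,
                h: int = 1, direction: str = NEGATIVE, seed: int = 0,
                measure_id: str = "", group: str = "") -> ConsistencyResult:
    """kappa for one measure: percent of m-patient subsamples whose
    one-tailed Spearman test is significant at alpha/h.

    Subsamples with a constant measure or constant durations are discarded
    (logged) and count as non-significant.
    """
    values = np.asarray(values, float)
    durations = np.asarray(durations, float)
    n = values.size
    if not (n > m >= 5):
        raise ValueError(f"need n_patients > m >= 5, got n={n}, m={m}")
    rng = np.random.default_rng(seed)
    idx = draw_subsets(rng, n_reps, n, m)
    v = values[idx]
    d = durations[idx]
    degenerate = (np.ptp(v, axis=1) == 0) | (np.ptp(d, axis=1) == 0)
    n_discarded = int(degenerate.sum())
    if n_discarded:
        logger.info("consistency: discarded %d degenerate subsamples",
                    n_discarded)
    rv = _rank_rows(v)
    rd = _rank_rows(d)
    rv -= rv.mean(axis=1, keepdims=True)
    rd -= rd.mean(axis=1, keepdims=True)
    denom = np.sqrt((rv ** 2).sum(axis=1) * (rd ** 2).sum(axis=1))
    denom[denom == 0] = np.nan
    rho = (rv * rd).sum(axis=1) / denom
    rho = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = rho * np.sqrt(m - 2) / np.sqrt(1 - rho ** 2)
    if direction == NEGATIVE:
        p = stats.t.cdf(t, m - 2)
        sign_ok = rho < 0
    else:
        p = stats.t.sf(t, m - 2)
        sign_ok = rho > 0
    significant = sign_ok & (p < alpha / h) & ~degenerate
    kappa = 100.0 * int(significant.sum()) / n_reps
    return ConsistencyResult(measure_id=measure_id, group=group,
                             subsample_size=m, n_reps=n_reps, kappa=kappa,
                             alpha=alpha, h=h, direction=direction,
                             rng_seed=seed, n_discarded=n_discarded)


def consistency_sweep(values: Sequence[float], durations: Sequence[float],
                      m_range: Iterable[int] = range(20, 31),
                      n_reps: int = 1000, alpha: float = 0.05, h: int = 1,
                      direction: str = NEGATIVE, seed: int = 0,
                      measure_id: str = "", group: str = ""
                      ) -> list[ConsistencyResult]:
    """One :func:`consistency` per subsample size m (the significance
    threshold scales with m, so kappa typically declines as m shrinks)."""
    results = []
    for m in m_range:
        sub_seed = int(np.random.default_rng([seed, m]).integers(2 ** 31))
        results.append(consistency(values, durations, m=m, n_reps=n_reps,
                                   alpha=alpha, h=h, direction=direction,
                                   seed=sub_seed, measure_id=measure_id,
                                   group=group))
    return results


def full_consistency_report(distances: DistanceSet,
                            subjects: Sequence[SubjectRecord], m: int = 30,
                            n_reps: int = 1000, alpha: float = 0.05,
                            seed: int = 0) -> list[ConsistencyResult]:
    """kappa per patient group for all 12 measures: ten tract z-scores
    (direction negative, h=10) and md_ipsi/md_contra (direction positive,
    h=2)."""
    frame = distances.frame
    results: list[ConsistencyResult] = []
    measures = [(f"z_{t}", NEGATIVE, H_UNIVARIATE) for t in TRACTS]
    measures += [("md_ipsi", POSITIVE, H_MULTIVARIATE),
                 ("md_contra", POSITIVE, H_MULTIVARIATE)]
    for gi, group in enumerate((Group.LEFT_TLE, Group.RIGHT_TLE)):
        members = [s for s in subjects if s.group is group]
        ids = [s.subject_id for s in members]
        durations = [s.duration_years for s in members]
        for mi, (measure, direction, h) in enumerate(measures):
            sub_seed = int(np.random.default_rng(
                [seed, gi, mi]).integers(2 ** 31))
            results.append(consistency(
                frame.loc[ids, measure].to_numpy(), durations, m=m,
                n_reps=n_reps, alpha=alpha, h=h, direction=direction,
                seed=sub_seed, measure_id=measure, group=group.value))
    return results


def consistency_to_frame(results: Sequence[ConsistencyResult]
                         ) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
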