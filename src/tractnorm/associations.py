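"""Spearman associations between distances and epilepsy duration.

One-tailed inference uses the Student-t approximation

    t = rho * sqrt(n - 2) / sqrt(1 - rho^2),   df = n - 2,

with the tail taken in the hypothesised direction: univariate z-scores are
hypothesised to become *more negative* with longer duration, Mahalanobis
distances *more positive*. Bonferroni correction uses h = 10 comparisons
for the tract-wise family and h = 2 for the two hemisphere distances.
A correlation whose sign opposes the hypothesis is never declared
significant, whatever its magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import TRACTS, Group, SubjectRecord
from .distances import DistanceSet
from .errors import DegenerateDataError

logger = logging.getLogger(__name__)

NEGATIVE = "negative"
POSITIVE = "positive"

H_UNIVARIATE = 10
H_MULTIVARIATE = 2


@dataclass
class AssociationResult:
    measure_id: str
    group: str
    rho: float
    n: int
    t_stat: float
    p_one_tailed: float
    direction: str
    h: int
    alpha: float = 0.05

    @property
    def significant_bonferroni(self) -> bool:
        sign_ok = (self.rho < 0) if self.direction == NEGATIVE \
            else (self.rho > 0)
        return bool(sign_ok and self.p_one_tailed < self.alpha / self.h)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (mean ranks for ties)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 4 or y.size != x.size:
        raise ValueError("need two equal-length vectors with n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("Spearman rho undefined for a constant "
                                  "vector")
    return float(stats.spearmanr(x, y).statistic)


def _t_from_rho(rho: float, n: int) -> float:
    return rho * np.sqrt(n - 2) / np.sqrt(1.0 - rho ** 2)


def one_tailed_p(rho: float, n: int, direction: str) -> float:
    """One-tailed p of a Spearman rho via the t approximation (df = n-2).

    A rho opposing the hypothesised direction gives p > 0.5; |rho| = 1
    returns 0 (logged; the t statistic is infinite).
    """
    if direction not in (NEGATIVE, POSITIVE):
        raise ValueError(f"unknown direction {direction!r}")
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(rho) >= 1.0:
        logger.info("one_tailed_p: |rho| = 1, t infinite, returning p = 0")
        sign_ok = (rho < 0) == (direction == NEGATIVE)
        return 0.0 if sign_ok else 1.0
    t = _t_from_rho(rho, n)
    if direction == NEGATIVE:
        return float(stats.t.cdf(t, n - 2))
    return float(stats.t.sf(t, n - 2))


def critical_rho(n: int, alpha: float = 0.05, h: int = 1,
                 direction: str = NEGATIVE) -> float:
    """The rho whose one-tailed p equals alpha / h, by inverting the t
    approximation: rho* = t* / sqrt(n - 2 + t*^2), signed per direction."""
    if n < 4:
        raise ValueError("need n >= 4")
    level = alpha / h
    if not 0 < level < 0.5:
        raise ValueError("alpha/h must lie in (0, 0.5)")
    t_star = stats.t.ppf(1.0 - level, n - 2)
    rho_star = t_star / np.sqrt(n - 2 + t_star ** 2)
    return float(-rho_star if direction == NEGATIVE else rho_star)


def duration_associations(distances: DistanceSet,
                          subjects: Sequence[SubjectRecord],
                          scope: str = "per_group",
                          alpha: float = 0.05) -> list[AssociationResult]:
    """Correlate every distance measure with epilepsy duration.

    ``per_group``: left- and right-TLE separately — ten tract z-scores
    (direction negative, h=10) and md_ipsi/md_contra (direction positive,
    h=2) each. ``combined``: all patients pooled on md_ipsi/md_contra only.
    """
    if scope not in ("per_group", "combined"):
        raise ValueError(f"unknown scope {scope!r}")
    patients = [s for s in subjects if s.is_patient]
    frame = distances.frame

    def correlate(members, measure, direction, h, label):
        ids = [s.subject_id for s in members]
        values = frame.loc[ids, measure].to_numpy()
        durations = np.array([s.duration_years for s in members])
        rho = spearman_rho(values, durations)
        return AssociationResult(
            measure_id=measure, group=label, rho=rho, n=len(members),
            t_stat=float(_t_from_rho(rho, len(members))),
            p_one_tailed=one_tailed_p(rho, len(members), direction),
            direction=direction, h=h, alpha=alpha)

    results: list[AssociationResult] = []
    if scope == "combined":
        if len(patients) < 4:
            raise ValueError("need >= 4 patients")
        for measure in ("md_ipsi", "md_contra"):
            results.append(correlate(patients, measure, POSITIVE,
                                     H_MULTIVARIATE, "combined"))
        return results

    for group in (Group.LEFT_TLE, Group.RIGHT_TLE):
        members = [s for s in patients if s.group is group]
        if len(members) < 4:
            raise ValueError(f"need >= 4 patients in {group.value}")
        for tract in TRACTS:
            results.append(correlate(members, f"z_{tract}", NEGATIVE,
                                     H_UNIVARIATE, group.value))
        for measure in ("md_ipsi", "md_contra"):
            results.append(correlate(members, measure, POSITIVE,
                                     H_MULTIVARIATE, group.value))
    return results


def associations_to_frame(results: Sequence[AssociationResult]
                          ) -> pd.DataFrame:
    rows = [{**vars(r), "significant_bonferroni": r.significant_bonferroni}
            for r in results]
    return pd.DataFrame(rows)
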