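"""Robust removal of sex and healthy-aging effects from tract FA.

Each tract is fitted with a Huber M-estimator solved by iteratively
reweighted least squares (IRLS): residuals within ``k`` robust scales keep
weight 1, larger residuals get weight ``k * scale / |residual|``. The scale
is re-estimated every iteration as median(|residual|) / 0.6745 (the MAD
normal-consistency factor). The residuals ("FAr") are what every downstream
distance and correlation consumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import TRACTS, Sex, SubjectRecord
from .errors import RankDeficientDesignError

#: 95%-efficiency Huber tuning constant (the conventional default).
HUBER_K = 1.345
MAD_FACTOR = 0.6745


@dataclass
class RobustFitResult:
    """Outcome of one Huber-IRLS fit.

    ``coefficients`` is always (intercept, age_slope, sex_offset); the sex
    entry is 0 when the sex column was constant and therefore dropped.
    """

    coefficients: np.ndarray
    final_weights: np.ndarray
    scale_estimate: float
    n_iterations: int
    converged: bool
    sex_dropped: bool = False


def huber_irls(X: np.ndarray, y: np.ndarray, k: float = HUBER_K,
               tol: float = 1e-8, max_iter: int = 100
               ) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    """Low-level Huber IRLS on an arbitrary design matrix.

    Returns (beta, weights, scale, n_iterations, converged). A rank-deficient
    design raises :class:`RankDeficientDesignError`. An exactly-fitting or
    constant response (robust scale ~ 0) terminates immediately with all
    weights 1.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficientDesignError(
            f"design matrix is rank deficient (shape {X.shape})")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    weights = np.ones(n)
    scale = 0.0
    y_span = max(1.0, float(np.max(np.abs(y))) if n else 1.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resid = y - X @ beta
        scale = float(np.median(np.abs(resid))) / MAD_FACTOR
        if scale <= 1e-12 * y_span:
            weights = np.ones(n)
            converged = True
            break
        u = np.abs(resid) / scale
        weights = np.where(u <= k, 1.0, k / np.maximum(u, 1e-300))
        sw = np.sqrt(weights)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    return beta, weights, scale, it, converged


def huber_irls_fit(age_years: Sequence[float], sex: Sequence,
                   response: Sequence[float], k: float = HUBER_K,
                   tol: float = 1e-8, max_iter: int = 100) -> RobustFitResult:
    """Huber-IRLS fit of ``response ~ 1 + age + sex`` (sex coded F=0, M=1).

    A constant sex column is dropped with a warning (its coefficient is
    reported as 0); constant age on top of that makes the design rank
    deficient and raises. Non-convergence is flagged, not raised.
    """
    age = np.asarray(age_years, float)
    y = np.asarray(response, float)
    if len(y) < 4:
        raise ValueError(f"need >= 4 observations, got {len(y)}")
    sex01 = np.array([1.0 if (s is Sex.M or s == "M" or s == 1) else 0.0
                      for s in sex])
    sex_dropped = bool(np.ptp(sex01) == 0)
    if sex_dropped:
        warnings.warn("sex column is constant; dropped from the covariate "
                      "model", RuntimeWarning, stacklevel=2)
        X = np.column_stack([np.ones_like(age), age])
    else:
        X = np.column_stack([np.ones_like(age), age, sex01])
    beta, w, scale, n_iter, conv = huber_irls(X, y, k=k, tol=tol,
                                              max_iter=max_iter)
    coef = np.zeros(3)
    coef[:len(beta)] = beta
    return RobustFitResult(coefficients=coef, final_weights=w,
                           scale_estimate=scale, n_iterations=n_iter,
                           converged=conv, sex_dropped=sex_dropped)


def predict(fit: RobustFitResult, age_years: np.ndarray,
            sex01: np.ndarray) -> np.ndarray:
    b0, b_age, b_sex = fit.coefficients
    return b0 + b_age * np.asarray(age_years, float) \
        + b_sex * np.asarray(sex01, float)


def residualize(fa_table: pd.DataFrame, subjects: Sequence[SubjectRecord],
                fit_population: str = "controls_only", k: float = HUBER_K,
                tol: float = 1e-8, max_iter: int = 100
                ) -> tuple[pd.DataFrame, dict[str, RobustFitResult]]:
    """Residualize every tract against age and sex.

    One robust fit per tract on the chosen population (``controls_only`` by
    default, so patients' disease effects cannot be absorbed into the
    healthy-aging model; ``all_subjects`` optionally), then applied to every
    subject: FAr = FA - (b0 + b_age*age + b_sex*sex).

    Returns (residual table, per-tract fits).
    """
    if fit_population not in ("controls_only", "all_subjects"):
        raise ValueError(f"unknown fit_population {fit_population!r}")
    order = [s.subject_id for s in subjects]
    fa = fa_table.loc[order]
    age = np.array([s.age_years for s in subjects])
    sex01 = np.array([1.0 if s.sex is Sex.M else 0.0 for s in subjects])
    if fit_population == "controls_only":
        mask = np.array([not s.is_patient for s in subjects])
        if not mask.any():
            raise ValueError("no controls available to fit the covariate "
                             "model")
    else:
        mask = np.ones(len(subjects), bool)

    fits: dict[str, RobustFitResult] = {}
    resid = pd.DataFrame(index=fa.index, columns=list(TRACTS), dtype=float)
    sex_labels = [s.sex for s in subjects]
    for tract in TRACTS:
        y = fa[tract].to_numpy()
        fit = huber_irls_fit(age[mask], [sex_labels[i] for i in
                                         np.flatnonzero(mask)],
                             y[mask], k=k, tol=tol, max_iter=max_iter)
        fits[tract] = fit
        resid[tract] = y - predict(fit, age, sex01)
    return resid, fits
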