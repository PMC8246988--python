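"""Normative distances: robust z-scores and shrinkage-covariance
Mahalanobis distances from the control distribution.

Each subject receives, per tract, a *robust z-score*: the median, over many
random control subsamples, of (FAr - subsample mean) / subsample SD; and per
hemisphere a *robust Mahalanobis distance*

    DM = sqrt((x - mu)' C^{-1} (x - mu)),

the median over the same subsampling protocol, where mu and C are the
subsample mean vector and a Ledoit-Wolf linearly-shrunk covariance of the
five same-hemisphere tract residuals. Shrinkage toward the scaled identity
keeps C well conditioned (and invertible) at subsample sizes barely above
the dimension. Controls are scored against the remaining controls
(leave-one-out); patients against all controls. Patients additionally get
their two hemisphere distances relabelled ipsilateral/contralateral.

Per-subject random streams are derived deterministically from
(seed, subject_id), so results do not depend on subject order.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .cohort import (
    LEFT_TRACTS, RIGHT_TRACTS, TRACTS, Group, SubjectRecord, hemisphere_map,
)
from .errors import DegenerateDataError, TooFewControlsError

logger = logging.getLogger(__name__)

LEDOIT_WOLF = "ledoit_wolf_linear"
SAMPLE = "sample"


@dataclass
class ShrinkageCovariance:
    """A symmetric positive-definite covariance estimate plus provenance."""

    matrix: np.ndarray
    shrinkage_intensity: float
    estimator_name: str = LEDOIT_WOLF


@dataclass
class DistanceSet:
    """Per-subject robust z-scores and Mahalanobis distances.

    ``frame`` is indexed by subject_id with columns ``z_<tract>`` for the
    ten tracts, ``md_left``/``md_right`` for every scored subject, and
    ``md_ipsi``/``md_contra`` (NaN for controls) after laterality
    relabelling.
    """

    frame: pd.DataFrame
    n_subsample: int
    n_reps: int
    rng_seed: int
    estimator_name: str = LEDOIT_WOLF

    def control_distances(self, subjects: Sequence[SubjectRecord]
                          ) -> np.ndarray:
        """The pooled control reference distances: md_left and md_right of
        every control (2 per control, e.g. 56 for 28 controls)."""
        ids = [s.subject_id for s in subjects if s.group is Group.CONTROL]
        sub = self.frame.loc[ids]
        return np.concatenate([sub["md_left"].to_numpy(),
                               sub["md_right"].to_numpy()])


# --------------------------------------------------------------------------
# Covariance shrinkage
# --------------------------------------------------------------------------

def ledoit_wolf_batch(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ledoit-Wolf linear shrinkage toward the scaled identity, batched.

    ``X`` has shape (..., n, p); returns (covariances (..., p, p),
    intensities (...)). The optimal intensity beta / delta is computed with
    the textbook n-denominator sample covariance; the returned matrix is
    then rescaled by n / (n - 1) so that the univariate (p = 1) case
    reduces exactly to the unbiased variance used by the z-scores.
    """
    X = np.asarray(X, float)
    n, p = X.shape[-2], X.shape[-1]
    Xc = X - X.mean(axis=-2, keepdims=True)
    XcT = Xc.swapaxes(-1, -2)
    S = (XcT @ Xc) / n
    mu = np.trace(S, axis1=-2, axis2=-1) / p
    eye = np.eye(p)
    centered = S - mu[..., None, None] * eye
    delta = (centered ** 2).sum(axis=(-2, -1)) / p
    X2 = Xc ** 2
    beta = ((X2.swapaxes(-1, -2) @ X2) / n - S ** 2
            ).sum(axis=(-2, -1)) / (p * n)
    beta = np.minimum(beta, delta)
    with np.errstate(invalid="ignore", divide="ignore"):
        intensity = np.where(delta > 0, beta / np.where(delta > 0, delta, 1.0),
                             0.0)
    shrunk = ((1.0 - intensity)[..., None, None] * S
              + (intensity * mu)[..., None, None] * eye)
    return shrunk * (n / (n - 1)), intensity


def shrinkage_covariance(samples: np.ndarray,
                         estimator: str = LEDOIT_WOLF) -> ShrinkageCovariance:
    """Covariance of an (n, p) sample, shrunk for stable inversion.

    ``ledoit_wolf_linear`` (default) is SPD whenever the sample is not fully
    degenerate; ``sample`` returns the unshrunk ddof-1 covariance.
    """
    samples = np.asarray(samples, float)
    if samples.ndim != 2:
        raise ValueError("samples must be a 2-D (n, p) array")
    n, p = samples.shape
    if n < 3:
        raise ValueError(f"need n >= 3 samples, got {n}")
    if estimator == SAMPLE:
        return ShrinkageCovariance(np.cov(samples, rowvar=False, ddof=1)
                                   .reshape(p, p), 0.0, SAMPLE)
    if estimator != LEDOIT_WOLF:
        raise ValueError(f"unknown estimator {estimator!r}")
    C, intensity = ledoit_wolf_batch(samples)
    if not np.all(np.linalg.eigvalsh(C) > 0):
        raise DegenerateDataError(
            "shrunk covariance is not positive definite (all samples "
            "identical?)")
    return ShrinkageCovariance(C, float(intensity), LEDOIT_WOLF)


# --------------------------------------------------------------------------
# Mahalanobis distance
# --------------------------------------------------------------------------

def mahalanobis(x: np.ndarray, mu: np.ndarray,
                C: ShrinkageCovariance | np.ndarray) -> float:
    """sqrt((x-mu)' C^{-1} (x-mu)) via a Cholesky solve (no explicit
    inverse). Raises :class:`DegenerateDataError` if C is not SPD."""
    matrix = C.matrix if isinstance(C, ShrinkageCovariance) else np.asarray(C, float)
    d = np.asarray(x, float) - np.asarray(mu, float)
    if matrix.shape != (d.size, d.size):
        raise ValueError("dimension mismatch between x, mu and C")
    try:
        factor = cho_factor(matrix, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(f"covariance not SPD: {exc}") from exc
    return float(np.sqrt(d @ cho_solve(factor, d)))


def _mahalanobis_batch(x: np.ndarray, mus: np.ndarray,
                       Cs: np.ndarray) -> np.ndarray:
    """Distances of a single point x to a batch of (mu, C) pairs."""
    d = x[None, :] - mus
    y = np.linalg.solve(Cs, d[..., None])[..., 0]
    return np.sqrt(np.einsum("...i,...i->...", d, y))


# --------------------------------------------------------------------------
# Subsampled (robust) distances
# --------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Deterministic per-subject stream derived from (seed, subject_id)."""
    sid_hash = zlib.crc32(subject_id.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng([seed, sid_hash])


def draw_subsets(rng: np.random.Generator, n_reps: int, m: int,
                 n_subsample: int, lead_shape: tuple = ()) -> np.ndarray:
    """Uniform random ``n_subsample``-subsets of range(m), one per rep,
    drawn without replacement within a rep.

    Implemented by arg-partitioning iid uniforms, which consumes the stream
    in a shape-independent row-major order.
    """
    if not n_subsample < m:
        raise ValueError(f"need n_subsample < m, got {n_subsample} >= {m}")
    u = rng.random(lead_shape + (n_reps, m))
    return np.argpartition(u, n_subsample, axis=-1)[..., :n_subsample]


def robust_zscore(value: float, reference: np.ndarray, n_subsample: int = 24,
                  n_reps: int = 1000, seed=0) -> float:
    """Median-of-subsamples z-score of ``value`` against ``reference``.

    Each rep draws ``n_subsample`` reference values without replacement and
    scores (value - mean) / SD (ddof=1); the median over reps is returned.
    Zero-variance subsamples are discarded (logged); if every rep is
    discarded the reference is degenerate and an error is raised.
    """
    reference = np.asarray(reference, float)
    m = reference.size
    if np.ptp(reference) == 0:
        raise DegenerateDataError("reference has zero variance")
    rng = _as_rng(seed)
    idx = draw_subsets(rng, n_reps, m, n_subsample)
    subs = reference[idx]
    means = subs.mean(axis=1)
    sds = subs.std(axis=1, ddof=1)
    ok = sds > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("robust_zscore: discarded %d zero-variance subsamples",
                    n_bad)
    if not ok.any():
        raise DegenerateDataError("all subsamples had zero variance")
    z = (value - means[ok]) / sds[ok]
    return float(np.median(z))


def robust_mahalanobis(x: np.ndarray, reference: np.ndarray,
                       n_subsample: int = 24, n_reps: int = 1000, seed=0,
                       estimator: str = LEDOIT_WOLF) -> float:
    """Median-of-subsamples Mahalanobis distance of ``x`` (p-vector) to an
    (m, p) reference; mu and the shrinkage covariance are re-estimated per
    subsample."""
    x = np.asarray(x, float)
    reference = np.asarray(reference, float)
    if reference.ndim == 1:
        reference = reference[:, None]
    if x.ndim == 0:
        x = x[None]
    m, p = reference.shape
    if not (m > n_subsample >= p + 2):
        raise ValueError(
            f"need m > n_subsample >= p+2, got m={m}, "
            f"n_subsample={n_subsample}, p={p}")
    rng = _as_rng(seed)
    idx = draw_subsets(rng, n_reps, m, n_subsample)
    subs = reference[idx]                       # (reps, nsub, p)
    if estimator == LEDOIT_WOLF:
        Cs, _ = ledoit_wolf_batch(subs)
    elif estimator == SAMPLE:
        ns = subs.shape[-2]
        Xc = subs - subs.mean(axis=-2, keepdims=True)
        Cs = np.einsum("...ij,...ik->...jk", Xc, Xc) / (ns - 1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    mus = subs.mean(axis=1)
    with np.errstate(invalid="ignore"):
        dists = _mahalanobis_batch(x, mus, Cs)
    ok = np.isfinite(dists)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("robust_mahalanobis: discarded %d degenerate subsamples",
                    n_bad)
    if not ok.any():
        raise DegenerateDataError("all subsamples were degenerate")
    return float(np.median(dists[ok]))


# --------------------------------------------------------------------------
# Whole-cohort distance set
# --------------------------------------------------------------------------

_Z_COLUMNS = tuple(f"z_{t}" for t in TRACTS)
_LEFT_IDX = np.array([TRACTS.index(t) for t in LEFT_TRACTS])
_RIGHT_IDX = np.array([TRACTS.index(t) for t in RIGHT_TRACTS])


def compute_distance_set(residuals: pd.DataFrame,
                         subjects: Sequence[SubjectRecord],
                         n_subsample: int = 24, n_reps: int = 1000,
                         seed: int = 0, estimator: str = LEDOIT_WOLF,
                         include_controls: bool = True) -> DistanceSet:
    """Score every subject against the control distribution.

    Controls are scored leave-one-out (their own row is removed from the
    reference before subsampling); patients are scored against all controls.
    Per subject: ten robust z-scores (one per tract), a left- and a
    right-hemisphere robust Mahalanobis distance over the five
    same-hemisphere tracts, and for patients ipsi/contra relabelling of the
    two. Requires enough controls that leave-one-out still exceeds the
    subsample size. ``include_controls=False`` restricts scoring to patients
    (controls still serve as the reference).
    """
    id_order = [s.subject_id for s in subjects]
    resid = residuals.loc[id_order]
    # Reference rows are canonicalised by sorted control id so that the
    # leave-one-out mapping (and hence every score) is independent of the
    # subject order handed in.
    control_ids = sorted(s.subject_id for s in subjects
                         if s.group is Group.CONTROL)
    n_controls = len(control_ids)
    if n_controls - 1 <= n_subsample:
        raise TooFewControlsError(
            f"{n_controls} controls cannot support leave-one-out "
            f"subsamples of {n_subsample}")
    R = resid.to_numpy()                      # (n_subjects, 10)
    ctrl = resid.loc[control_ids].to_numpy()  # (nc, 10)
    ctrl_T = ctrl.T                           # (10, nc)

    scored = [s for s in subjects
              if include_controls or s.is_patient]
    rows = {}
    control_rank = {sid: k for k, sid in enumerate(control_ids)}
    pos_of = {sid: i for i, sid in enumerate(id_order)}
    for s in scored:
        i = pos_of[s.subject_id]
        rng = subject_rng(seed, s.subject_id)
        if s.group is Group.CONTROL:
            k = control_rank[s.subject_id]
            keep = np.concatenate([np.arange(k),
                                   np.arange(k + 1, n_controls)])
        else:
            keep = np.arange(n_controls)
        m = keep.size
        x = R[i]

        # Ten per-tract z-scores: one fresh subset draw per tract, in
        # canonical tract order, from this subject's stream.
        idx_z = keep[draw_subsets(rng, n_reps, m, n_subsample,
                                  lead_shape=(len(TRACTS),))]
        subs = ctrl_T[np.arange(len(TRACTS))[:, None, None], idx_z]
        means = subs.mean(axis=2)
        sds = subs.std(axis=2, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (x[:, None] - means) / sds
        if (sds > 0).all():
            z_med = np.median(z, axis=1)
        else:
            z_med = np.nanmedian(np.where(sds > 0, z, np.nan), axis=1)

        # Two hemisphere Mahalanobis distances (left drawn first).
        idx_md = keep[draw_subsets(rng, n_reps, m, n_subsample,
                                   lead_shape=(2,))]
        md = np.empty(2)
        for h, cols in enumerate((_LEFT_IDX, _RIGHT_IDX)):
            subs_h = ctrl[:, cols][idx_md[h]]       # (reps, nsub, 5)
            if estimator == LEDOIT_WOLF:
                Cs, _ = ledoit_wolf_batch(subs_h)
            else:
                ns = subs_h.shape[-2]
                Xc = subs_h - subs_h.mean(axis=-2, keepdims=True)
                Cs = np.einsum("...ij,...ik->...jk", Xc, Xc) / (ns - 1)
            mus = subs_h.mean(axis=1)
            with np.errstate(invalid="ignore"):
                dists = _mahalanobis_batch(x[cols], mus, Cs)
            if np.isfinite(dists).all():
                md[h] = np.median(dists)
            else:
                md[h] = np.nanmedian(
                    np.where(np.isfinite(dists), dists, np.nan))

        row = dict(zip(_Z_COLUMNS, z_med))
        row["md_left"], row["md_right"] = md
        if s.is_patient:
            if s.group is Group.LEFT_TLE:
                row["md_ipsi"], row["md_contra"] = md[0], md[1]
            else:
                row["md_ipsi"], row["md_contra"] = md[1], md[0]
        else:
            row["md_ipsi"] = row["md_contra"] = np.nan
        rows[s.subject_id] = row

    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject_id"
    frame = frame[list(_Z_COLUMNS) + ["md_left", "md_right", "md_ipsi",
                                      "md_contra"]]
    return DistanceSet(frame=frame, n_subsample=n_subsample, n_reps=n_reps,
                       rng_seed=seed, estimator_name=estimator)
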