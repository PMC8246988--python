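"""Extrapolation of the Mahalanobis distance to epilepsy duration zero.

A Huber-IRLS regression DM_i = beta0 + beta1 * duration_i + eps_i on the
pooled (ipsi/contra-relabelled) patient distances gives the estimated
distance at onset, beta0. Because Mahalanobis distances are positively
skewed, beta0 and the pooled control distances (two per control: one per
hemisphere) are log-transformed (natural log; the base cancels in a
z-score) and beta0 is scored with the same median-of-subsamples robust-z
protocol used for the distances, with the subsample size scaled to the
control-distance count (default 54 of 56). The two-tailed p comes from the
standard normal: no direction is hypothesised at onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .covariates import HUBER_K, huber_irls
from .errors import DegenerateDataError
from .distances import robust_zscore

IPSILATERAL = "ipsilateral"
CONTRALATERAL = "contralateral"


@dataclass
class OnsetExtrapolation:
    side: str
    beta0: float
    beta1: float
    control_log_mean: float
    control_log_sd: float
    z_intercept: float
    p_two_tailed: float
    n_subsample: int
    n_reps: int


def extrapolate_onset(patient_md: Sequence[float],
                      durations: Sequence[float],
                      control_md: Sequence[float],
                      side: str = IPSILATERAL,
                      n_subsample: int = 54, n_reps: int = 1000,
                      seed=0, huber_k: float = HUBER_K) -> OnsetExtrapolation:
    """Estimate the distance at duration zero and its deviation from
    controls.

    ``patient_md``/``durations`` are the pooled patient distances for one
    side; ``control_md`` is the pooled control distance distribution. All
    distances must be positive (they are logged); durations must vary.
    """
    md = np.asarray(patient_md, float)
    dur = np.asarray(durations, float)
    ctrl = np.asarray(control_md, float)
    if md.size == 0 or dur.size != md.size:
        raise ValueError("need matching, non-empty patient distances and "
                         "durations")
    if md.size < 4:
        raise ValueError("need >= 4 patients")
    if (md <= 0).any() or (ctrl <= 0).any():
        raise DegenerateDataError("non-positive distance: log undefined")
    if np.ptp(dur) == 0:
        raise DegenerateDataError("degenerate durations (all equal)")
    X = np.column_stack([np.ones_like(dur), dur])
    beta, *_ = huber_irls(X, md, k=huber_k)
    beta0, beta1 = float(beta[0]), float(beta[1])
    if beta0 <= 0:
        raise DegenerateDataError(
            f"extrapolated distance at onset is non-positive ({beta0})")
    log_ctrl = np.log(ctrl)
    z = robust_zscore(np.log(beta0), log_ctrl, n_subsample=n_subsample,
                      n_reps=n_reps, seed=seed)
    return OnsetExtrapolation(
        side=side, beta0=beta0, beta1=beta1,
        control_log_mean=float(log_ctrl.mean()),
        control_log_sd=float(log_ctrl.std(ddof=1)),
        z_intercept=float(z),
        p_two_tailed=float(2.0 * stats.norm.sf(abs(z))),
        n_subsample=n_subsample, n_reps=n_reps)
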