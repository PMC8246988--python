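"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes: a three-group
cohort (controls, left-TLE, right-TLE), tract-mean FA values in (0, 1) with
positive inter-tract covariance, linear healthy-aging and sex effects, a
negative FA-versus-epilepsy-duration trend that is stronger ipsilateral to
the focus, per-patient heterogeneity in *which* tracts carry the duration
effect, and optional gross outliers.

The FA of subject *i* in tract *j* is

    FA_ij = mean_j + age_slope * age_i + sex_offset * 1[male_i]
            + slope_side(j) * duration_i * (1 + L_ij)       (patients only)
            - outcome_deficit * 1[contra, not seizure free] (patients only)
            + correlated Gaussian noise,

with L_ij ~ N(0, heterogeneity_sd) the per-patient tract loading. Draws
leaving (0, 1) are clipped with an explicit warning (never silently).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    TRACTS, Group, HemisphereMap, Outcome, Sex, SubjectRecord, hemisphere_map,
)
from .errors import ConfigError

N_TRACTS = len(TRACTS)

#: Plausible adult tract-mean FA per tract (dimensionless), bilateral pairs.
DEFAULT_TRACT_MEAN_FA = np.array(
    [0.44, 0.44, 0.50, 0.50, 0.42, 0.42, 0.35, 0.35, 0.45, 0.45])


def exchangeable_correlation(within: float = 0.4,
                             across: float = 0.3) -> np.ndarray:
    """Exchangeable inter-tract correlation: ``within`` for same-hemisphere
    pairs, ``across`` for cross-hemisphere pairs, 1 on the diagonal."""
    same_hemi = np.equal.outer(
        [t[-1] for t in TRACTS], [t[-1] for t in TRACTS])
    corr = np.where(same_hemi, within, across)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort; defaults emulate the study conditions
    (group sizes 28/33/33, sex/outcome/HS splits, adult ages, long chronic
    durations)."""

    n_control: int = 28
    n_left: int = 33
    n_right: int = 33
    tract_mean_fa: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRACT_MEAN_FA.copy())
    inter_tract_correlation: np.ndarray = field(
        default_factory=exchangeable_correlation)
    tract_sd: np.ndarray = field(
        default_factory=lambda: np.full(N_TRACTS, 0.02))
    age_slope_per_year: float = -4e-4
    sex_offset: float = 0.005          # additive FA offset for males
    duration_slope_ipsi: float = -6e-4   # FA per year of epilepsy duration
    duration_slope_contra: float = -2e-4
    heterogeneity_sd: float = 0.5      # SD of per-patient tract loadings
    outlier_fraction: float = 0.0      # fraction of (subject, tract) cells
    outlier_magnitude_sd: float = 0.06
    outcome_deficit_contra: float = 0.0  # extra contra FA deficit, ILAE2+
    age_range: tuple[float, float] = (18.0, 60.0)
    onset_range: tuple[float, float] = (1.0, 30.0)
    female_frac_control: float = 16 / 28
    female_frac_left: float = 17 / 33
    female_frac_right: float = 24 / 33
    ilae1_frac_left: float = 18 / 33
    ilae1_frac_right: float = 15 / 33
    hs_frac_left: float = 28 / 33
    hs_frac_right: float = 20 / 33
    rng_seed: int = 0

    def validate(self) -> None:
        corr = np.asarray(self.inter_tract_correlation, float)
        if corr.shape != (N_TRACTS, N_TRACTS):
            raise ConfigError(f"correlation matrix must be "
                              f"{N_TRACTS}x{N_TRACTS}, got {corr.shape}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ConfigError("correlation matrix is not symmetric")
        if np.linalg.eigvalsh(corr).min() <= 0:
            raise ConfigError("correlation matrix is not positive definite")
        sds = np.asarray(self.tract_sd, float)
        if sds.shape != (N_TRACTS,) or (sds <= 0).any():
            raise ConfigError("tract_sd must be 10 positive values")
        means = np.asarray(self.tract_mean_fa, float)
        if means.shape != (N_TRACTS,) or ((means <= 0) | (means >= 1)).any():
            raise ConfigError("tract_mean_fa must be 10 values in (0,1)")
        for n, name in ((self.n_control, "n_control"),
                        (self.n_left, "n_left"), (self.n_right, "n_right")):
            if n < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigError("outlier_fraction must be in [0,1)")
        if self.heterogeneity_sd < 0:
            raise ConfigError("heterogeneity_sd must be non-negative")

    # Named scenarios -----------------------------------------------------

    @classmethod
    def null_effects(cls, **overrides) -> "GeneratorConfig":
        """All systematic effects switched off: patients and controls are
        identical in law (for type-I-error / calibration studies)."""
        base = dict(age_slope_per_year=0.0, sex_offset=0.0,
                    duration_slope_ipsi=0.0, duration_slope_contra=0.0,
                    heterogeneity_sd=0.0, outlier_fraction=0.0,
                    outcome_deficit_contra=0.0)
        base.update(overrides)
        return cls(**base)

    @classmethod
    def strong_heterogeneous_ipsilateral(cls, **overrides) -> "GeneratorConfig":
        """A pronounced ipsilateral duration effect whose per-patient tract
        loadings vary widely, so different tracts are hit in different
        patients — the regime where a hemisphere-level multivariate distance
        should outperform any single-tract analysis."""
        base = dict(duration_slope_ipsi=-6e-4, duration_slope_contra=-2e-4,
                    heterogeneity_sd=1.8)
        base.update(overrides)
        return cls(**base)


def _allocate_binary(rng: np.random.Generator, n: int, frac: float) -> np.ndarray:
    """Boolean vector with round(frac*n) True entries in random positions."""
    k = int(round(frac * n))
    flags = np.zeros(n, bool)
    flags[:k] = True
    rng.shuffle(flags)
    return flags


def generate_cohort(config: GeneratorConfig, seed: int | None = None
                    ) -> tuple[list[SubjectRecord], pd.DataFrame]:
    """Draw a full synthetic cohort.

    Returns (subject records sorted by id, tract-FA DataFrame aligned to
    them). Byte-identical output for a fixed config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)

    groups = ([Group.CONTROL] * config.n_control
              + [Group.LEFT_TLE] * config.n_left
              + [Group.RIGHT_TLE] * config.n_right)
    prefixes = {Group.CONTROL: "C", Group.LEFT_TLE: "L", Group.RIGHT_TLE: "R"}
    counters: dict[Group, int] = {g: 0 for g in Group}
    ids = []
    for g in groups:
        counters[g] += 1
        ids.append(f"{prefixes[g]}{counters[g]:03d}")

    n_total = len(groups)
    age_lo, age_hi = config.age_range
    onset_lo, onset_hi = config.onset_range
    female_fracs = {Group.CONTROL: config.female_frac_control,
                    Group.LEFT_TLE: config.female_frac_left,
                    Group.RIGHT_TLE: config.female_frac_right}

    records: list[SubjectRecord] = []
    for g in (Group.CONTROL, Group.LEFT_TLE, Group.RIGHT_TLE):
        members = [i for i, gg in enumerate(groups) if gg is g]
        n = len(members)
        if n == 0:
            continue
        female = _allocate_binary(rng, n, female_fracs[g])
        ages = rng.uniform(age_lo, age_hi, size=n)
        if g is Group.CONTROL:
            for j, i in enumerate(members):
                records.append(SubjectRecord(
                    subject_id=ids[i], group=g,
                    sex=Sex.F if female[j] else Sex.M,
                    age_years=round(float(ages[j]), 2)))
            continue
        # Onset uniform on onset_range, duration = age - onset by
        # construction; rejection keeps duration >= 1 year.
        onsets = rng.uniform(onset_lo, onset_hi, size=n)
        for j in range(n):
            while ages[j] - onsets[j] < 1.0:
                ages[j] = rng.uniform(age_lo, age_hi)
                onsets[j] = rng.uniform(onset_lo, onset_hi)
        ilae_frac = (config.ilae1_frac_left if g is Group.LEFT_TLE
                     else config.ilae1_frac_right)
        hs_frac = (config.hs_frac_left if g is Group.LEFT_TLE
                   else config.hs_frac_right)
        ilae1 = _allocate_binary(rng, n, ilae_frac)
        hs = _allocate_binary(rng, n, hs_frac)
        for j, i in enumerate(members):
            age = round(float(ages[j]), 2)
            onset = round(float(onsets[j]), 2)
            records.append(SubjectRecord(
                subject_id=ids[i], group=g,
                sex=Sex.F if female[j] else Sex.M,
                age_years=age, onset_age_years=onset,
                duration_years=round(age - onset, 2),
                ilae_outcome=Outcome.ILAE1 if ilae1[j] else Outcome.ILAE2PLUS,
                hs_present=bool(hs[j])))

    records.sort(key=lambda r: r.subject_id)
    for r in records:
        r.validate()

    # FA matrix in record order.
    means = np.asarray(config.tract_mean_fa, float)
    sds = np.asarray(config.tract_sd, float)
    cov_chol = np.linalg.cholesky(
        np.asarray(config.inter_tract_correlation, float)
        * np.outer(sds, sds))
    fa = np.tile(means, (n_total, 1))
    ages_arr = np.array([r.age_years for r in records])
    male = np.array([r.sex is Sex.M for r in records], float)
    fa += config.age_slope_per_year * ages_arr[:, None]
    fa += config.sex_offset * male[:, None]

    slope_by_tract = {Group.LEFT_TLE: np.empty(N_TRACTS),
                      Group.RIGHT_TLE: np.empty(N_TRACTS)}
    for g, slopes in slope_by_tract.items():
        hmap: HemisphereMap = hemisphere_map(g)
        for j, t in enumerate(TRACTS):
            slopes[j] = (config.duration_slope_ipsi
                         if t in hmap.ipsilateral_tracts
                         else config.duration_slope_contra)

    for i, r in enumerate(records):
        if not r.is_patient:
            continue
        loadings = rng.normal(0.0, config.heterogeneity_sd, size=N_TRACTS) \
            if config.heterogeneity_sd > 0 else np.zeros(N_TRACTS)
        fa[i] += (slope_by_tract[r.group] * r.duration_years
                  * (1.0 + loadings))
        if (config.outcome_deficit_contra != 0.0
                and r.ilae_outcome is Outcome.ILAE2PLUS):
            contra = hemisphere_map(r.group).contralateral_tracts
            for j, t in enumerate(TRACTS):
                if t in contra:
                    fa[i, j] -= config.outcome_deficit_contra

    fa += rng.standard_normal((n_total, N_TRACTS)) @ cov_chol.T

    if config.outlier_fraction > 0:
        n_cells = n_total * N_TRACTS
        n_out = int(round(config.outlier_fraction * n_cells))
        cells = rng.choice(n_cells, size=n_out, replace=False)
        shocks = rng.normal(0.0, config.outlier_magnitude_sd, size=n_out)
        fa.flat[cells] += shocks

    out_of_range = int(((fa <= 0) | (fa >= 1)).sum())
    if out_of_range:
        warnings.warn(
            f"{out_of_range} generated FA values fell outside (0,1) and "
            "were clipped", RuntimeWarning, stacklevel=2)
        fa = np.clip(fa, 1e-3, 1 - 1e-3)

    fa_df = pd.DataFrame(fa, index=pd.Index([r.subject_id for r in records],
                                            name="subject_id"),
                         columns=list(TRACTS))
    return records, fa_df


def config_to_dict(config: GeneratorConfig) -> dict:
    """JSON/YAML-serialisable echo of a config (arrays become lists)."""
    d = dataclasses.asdict(config)
    for key, value in d.items():
        if isinstance(value, np.ndarray):
            d[key] = value.tolist()
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    kwargs = dict(d)
    for key in ("tract_mean_fa", "inter_tract_correlation", "tract_sd"):
        if key in kwargs:
            kwargs[key] = np.asarray(kwargs[key], float)
    for key in ("age_range", "onset_range"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    unknown = set(kwargs) - {f.name for f in dataclasses.fields(GeneratorConfig)}
    if unknown:
        raise ConfigError(f"unknown generator config keys: {sorted(unknown)}")
    return GeneratorConfig(**kwargs)
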