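"""End-to-end pipeline: cohort -> residuals -> distances -> statistics.

A single :class:`PipelineConfig` (typically loaded from YAML) names either
a pair of input CSVs or a synthetic-generator section (exactly one of the
two), plus the knobs of every stage and one top-level seed from which all
stage streams are derived. :func:`run_pipeline` writes

    distances.csv, associations.csv, onset.json, cohort_tests.csv,
    outcome_tests.csv, consistency.csv, run_manifest.json

into the output directory and is byte-identical on rerun with the same
config and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associations import associations_to_frame, duration_associations
from .cohort import Group, SubjectRecord, read_cohort
from .cohort_tests import (
    demographic_tests, normality_report, outcome_comparison, tests_to_frame,
)
from .covariates import residualize
from .distances import LEDOIT_WOLF, DistanceSet, compute_distance_set
from .errors import ConfigError
from .onset import CONTRALATERAL, IPSILATERAL, extrapolate_onset
from .robustness import consistency_to_frame, full_consistency_report
from .synthetic import GeneratorConfig, config_from_dict, config_to_dict, \
    generate_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    demographics_path: str | None = None
    fa_path: str | None = None
    generator: GeneratorConfig | None = None
    out_dir: str = "tractnorm_out"
    seed: int = 0
    covariates_fit_population: str = "controls_only"
    covariates_huber_k: float = 1.345
    covariates_max_iter: int = 100
    covariates_tol: float = 1e-8
    distances_n_subsample: int = 24
    distances_n_reps: int = 1000
    distances_estimator: str = LEDOIT_WOLF
    association_alpha: float = 0.05
    onset_n_reps: int = 1000
    robustness_m: int = 30
    robustness_n_reps: int = 1000
    run_outcome_tests: bool = True

    def validate(self) -> None:
        have_paths = self.demographics_path is not None or \
            self.fa_path is not None
        if have_paths and self.generator is not None:
            raise ConfigError("config must name input paths OR a generator "
                              "section, not both")
        if not have_paths and self.generator is None:
            raise ConfigError("config must name input paths or a generator "
                              "section")
        if have_paths and (self.demographics_path is None
                           or self.fa_path is None):
            raise ConfigError("both demographics_path and fa_path are "
                              "required for file input")


def config_from_yaml(path: str | Path) -> PipelineConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return pipeline_config_from_dict(raw)


def pipeline_config_from_dict(raw: dict) -> PipelineConfig:
    raw = dict(raw)
    gen = raw.pop("generator", None)
    inputs = raw.pop("input", {}) or {}
    cfg_kwargs = {}
    for section, prefix in (("covariates", "covariates_"),
                            ("distances", "distances_"),
                            ("association", "association_"),
                            ("onset", "onset_"),
                            ("robustness", "robustness_")):
        for key, value in (raw.pop(section, {}) or {}).items():
            cfg_kwargs[prefix + key] = value
    cfg_kwargs.update(raw)
    if inputs:
        cfg_kwargs["demographics_path"] = inputs.get("demographics")
        cfg_kwargs["fa_path"] = inputs.get("tract_fa")
    if gen is not None:
        cfg_kwargs["generator"] = config_from_dict(gen)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(cfg_kwargs) - known
    if unknown:
        raise ConfigError(f"unknown pipeline config keys: {sorted(unknown)}")
    config = PipelineConfig(**cfg_kwargs)
    config.validate()
    return config


def _derived_seed(seed: int, stage: int) -> int:
    return int(np.random.default_rng([seed, stage]).integers(2 ** 31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle; returns the
    in-memory results keyed by stage."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.generator is not None:
        subjects, fa = generate_cohort(config.generator,
                                       seed=_derived_seed(config.seed, 0))
        source = "synthetic"
    else:
        subjects, fa = read_cohort(config.demographics_path, config.fa_path)
        source = "files"
    n_patients = sum(s.is_patient for s in subjects)
    logger.info("cohort: %d subjects (%d patients) from %s",
                len(subjects), n_patients, source)

    residuals, fits = residualize(
        fa, subjects, fit_population=config.covariates_fit_population,
        k=config.covariates_huber_k, tol=config.covariates_tol,
        max_iter=config.covariates_max_iter)
    logger.info("residualized %d tracts (fit on %s)", residuals.shape[1],
                config.covariates_fit_population)

    dist_seed = _derived_seed(config.seed, 1)
    distances = compute_distance_set(
        residuals, subjects, n_subsample=config.distances_n_subsample,
        n_reps=config.distances_n_reps, seed=dist_seed,
        estimator=config.distances_estimator)
    logger.info("distances: %d subjects x %d reps", len(distances.frame),
                config.distances_n_reps)

    associations = duration_associations(
        distances, subjects, scope="per_group",
        alpha=config.association_alpha)
    associations += duration_associations(
        distances, subjects, scope="combined",
        alpha=config.association_alpha)

    patients = [s for s in subjects if s.is_patient]
    control_md = distances.control_distances(subjects)
    onset_seed = _derived_seed(config.seed, 2)
    n_ctrl_dist = control_md.size
    onset_results = {}
    for side, column in ((IPSILATERAL, "md_ipsi"),
                         (CONTRALATERAL, "md_contra")):
        res = extrapolate_onset(
            distances.frame.loc[[s.subject_id for s in patients],
                                column].to_numpy(),
            [s.duration_years for s in patients], control_md, side=side,
            n_subsample=n_ctrl_dist - 2, n_reps=config.onset_n_reps,
            seed=onset_seed, huber_k=config.covariates_huber_k)
        onset_results[side] = res

    cohort_results = demographic_tests(subjects)
    control_resid = residuals.loc[[s.subject_id for s in subjects
                                   if s.group is Group.CONTROL]]
    cohort_results += normality_report(control_resid,
                                       alpha=config.association_alpha,
                                       seed=_derived_seed(config.seed, 3))

    outcome_results = []
    if config.run_outcome_tests:
        has_outcomes = all(
            any(s.group is g and s.ilae_outcome is not None
                for s in patients)
            for g in (Group.LEFT_TLE, Group.RIGHT_TLE))
        if has_outcomes:
            outcome_results = outcome_comparison(
                distances, subjects, alpha=config.association_alpha)
        else:
            logger.info("outcome labels incomplete; outcome tests skipped")

    robust_seed = _derived_seed(config.seed, 4)
    consistency_results = full_consistency_report(
        distances, subjects, m=config.robustness_m,
        n_reps=config.robustness_n_reps, alpha=config.association_alpha,
        seed=robust_seed)

    # ---- write the bundle -----------------------------------------------
    distances.frame.to_csv(out_dir / "distances.csv")
    associations_to_frame(associations).to_csv(
        out_dir / "associations.csv", index=False)
    with open(out_dir / "onset.json", "w", encoding="utf-8") as fh:
        json.dump({side: vars(res) for side, res in onset_results.items()},
                  fh, indent=2)
    tests_to_frame(cohort_results).to_csv(out_dir / "cohort_tests.csv",
                                          index=False)
    tests_to_frame(outcome_results).to_csv(out_dir / "outcome_tests.csv",
                                           index=False)
    consistency_to_frame(consistency_results).to_csv(
        out_dir / "consistency.csv", index=False)

    manifest = {
        "tractnorm_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "source": source,
        "n_subjects": len(subjects),
        "n_patients": n_patients,
        "seed": config.seed,
        "derived_seeds": {"generator": _derived_seed(config.seed, 0),
                          "distances": dist_seed, "onset": onset_seed,
                          "normality": _derived_seed(config.seed, 3),
                          "robustness": robust_seed},
        "config": _config_echo(config),
    }
    with open(out_dir / "run_manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)

    return {"subjects": subjects, "fa": fa, "residuals": residuals,
            "covariate_fits": fits, "distances": distances,
            "associations": associations, "onset": onset_results,
            "cohort_tests": cohort_results, "outcome_tests": outcome_results,
            "consistency": consistency_results, "manifest": manifest}


def _config_echo(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    if config.generator is not None:
        d["generator"] = config_to_dict(config.generator)
    return d
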