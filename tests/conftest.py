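import numpy as np
import pytest

from tractnorm.covariates import residualize
from tractnorm.distances import compute_distance_set
from tractnorm.synthetic import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One seeded draw of the default synthetic cohort (28/33/33)."""
    return generate_cohort(GeneratorConfig(), seed=11)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with every systematic effect switched off."""
    return generate_cohort(GeneratorConfig.null_effects(), seed=12)


@pytest.fixture(scope="session")
def default_residuals(default_cohort):
    subjects, fa = default_cohort
    resid, _ = residualize(fa, subjects)
    return resid


@pytest.fixture(scope="session")
def default_distances(default_cohort, default_residuals):
    """A reduced-rep distance set for the default cohort; 200 reps keeps
    the suite fast while leaving the medians stable to ~0.05."""
    subjects, _ = default_cohort
    return compute_distance_set(default_residuals, subjects, n_reps=200,
                                seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
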