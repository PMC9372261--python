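import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from modmod import (
    DEFAULT_COEFFICIENTS,
    GeneratorConfig,
    ModelFit,
    ModelSpec,
    cohort_with_band_counts,
    fit_model,
    generate_cohort,
    score_frame,
    screen_positive,
)

#: Severity-band breakdown and contamination mix of the reference screening
#: fixture: 2,359 raw records, 112 contaminated, 2,247 retained, 694 positive.
FIXTURE_BAND_COUNTS = {
    "none": 1553,
    "mild": 591,
    "moderate": 70,
    "moderately_severe": 23,
    "severe": 10,
}
FIXTURE_CONTAMINATION = {"incomplete": 48, "straight_line": 36, "patterned": 28}


@pytest.fixture(scope="session")
def clean_cohort():
    """Clean synthetic cohort at the default (study-structure) configuration."""
    return generate_cohort(GeneratorConfig(n_respondents=5000, seed=101))


@pytest.fixture(scope="session")
def clean_scores(clean_cohort):
    return score_frame(clean_cohort)


@pytest.fixture(scope="session")
def screening_fixture_cohort():
    """Cohort with exact band counts and contamination of the reference survey."""
    return cohort_with_band_counts(
        FIXTURE_BAND_COUNTS, FIXTURE_CONTAMINATION, seed=7
    )


@pytest.fixture(scope="session")
def reported_fit():
    """Desk-constructed Model-3 fit carrying the reported coefficient vector."""
    return ModelFit.from_coefficients(DEFAULT_COEFFICIENTS, n=694)


@pytest.fixture(scope="session")
def fitted_model3(clean_scores):
    """Model 3 estimated on the screened synthetic score table."""
    screened = screen_positive(clean_scores)
    return fit_model(screened, ModelSpec(model_id=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
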