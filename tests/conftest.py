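import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import distarget as dt

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def frs_spec():
    return dt.make_survey_template("frs_like")


@pytest.fixture(scope="session")
def frs_truth(frs_spec):
    return dt.default_true_params(frs_spec)


@pytest.fixture(scope="session")
def small_survey(frs_spec, frs_truth):
    """~800-person one-factor survey used across unit tests."""
    cfg = dt.GeneratorConfig(n_households=dt.households_for_persons(800), seed=42)
    data, spec, truth = dt.generate_survey(cfg, frs_spec, frs_truth)
    return data


@pytest.fixture(scope="session")
def small_fit(small_survey, frs_spec):
    """One shared fitted model (reduced quadrature keeps the suite fast)."""
    return dt.fit_model(
        small_survey, frs_spec, dt.FitOptions(quadrature_points=11)
    )
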