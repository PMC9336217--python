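import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

# arviz emits a refactor FutureWarning on import; irrelevant here
warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

settings.register_profile(
    "ci",
    deadline=None,
    max_examples=50,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from saeintervals.design import DesignSpec, build_design  # noqa: E402
from saeintervals.glmm import fit_glmm  # noqa: E402
from saeintervals.synthetic import GeneratorConfig, generate_world  # noqa: E402


@pytest.fixture(scope="session")
def small_world():
    """A small but fittable world: 8 counties x 120 respondents."""
    return generate_world(GeneratorConfig(
        n_counties=8, n_per_county=120, seed=42,
        prevalence_preset="arthritis",  # common outcome keeps cells informative
    ))


@pytest.fixture(scope="session")
def small_design(small_world):
    spec = DesignSpec()
    X, y, cidx, cids = build_design(small_world.survey, small_world.covariates, spec)
    return X, y, cidx, cids, spec


@pytest.fixture(scope="session")
def small_fit(small_design):
    X, y, cidx, cids, spec = small_design
    return fit_glmm(X, y, cidx, cids, column_names=spec.column_names)


@pytest.fixture(scope="session")
def tiny_world():
    """3 counties x 12 respondents: small enough for brute-force oracles."""
    return generate_world(GeneratorConfig(
        n_counties=3, n_per_county=12, seed=5,
        county_pop_range=(5_000, 20_000),
    ))


def rng(seed=0):
    return np.random.default_rng(seed)
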