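import numpy as np
import pytest
from hypothesis import settings

from tppunish import (
    FitConfig,
    ModelParams,
    StudyDesign,
    build_design,
    get_model,
    simulate_choices,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_design():
    return build_design(StudyDesign(), seed=11)


@pytest.fixture(scope="session")
def hp_model():
    return get_model("hyperbolic_punishment")


@pytest.fixture(scope="session")
def hp_params():
    return ModelParams(gamma_sd=0.5, k=0.1, beta=1.0)


@pytest.fixture(scope="session")
def hp_dataset(default_design, hp_model, hp_params):
    """One simulated subject under the hyperbolic punishment model."""
    return simulate_choices(default_design, hp_model, hp_params, seed=7,
                            subject_id="sub-001")


@pytest.fixture(scope="session")
def quick_fit_config():
    return FitConfig(n_restarts=4, seed=0)
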