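import numpy as np
import pytest
from hypothesis import settings

from mabvisc import ModelSpec, SyntheticSpec, gen_viscosity_profile

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

MODEL_TRUTHS = {
    "growth_exponential": {"Y0": 2.0, "k": 0.02},
    "three_param_exponential": {"a1": 0.5, "a2": 0.025, "a3": 0.0},
    "ross_minton": {"intrinsic_viscosity": 0.0063, "crowding_ratio": 0.3},
    "tomar": {"lnA": -0.58, "B": 0.0208},
}


@pytest.fixture(scope="session")
def model_truths():
    return MODEL_TRUTHS


@pytest.fixture
def noiseless_profile():
    def make(model_name, grid=tuple(float(c) for c in range(10, 241, 10))):
        spec = ModelSpec(model_name, MODEL_TRUTHS[model_name])
        return gen_viscosity_profile(
            spec, SyntheticSpec(seed=0, sd_value=0.0), grid=grid
        )
    return make
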