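import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import soiltrial as st

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_trial():
    """One default synthetic trial (seed 1), shared read-only."""
    return st.generate_trial(st.default_config(seed=1))


@pytest.fixture()
def noise_free_config():
    """Default config with every noise source switched off."""
    return dataclasses.replace(
        st.default_config(seed=0), block_sd=0.0, residual_sd=0.0, indicator_cv=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
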