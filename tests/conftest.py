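import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def null_cohort():
    """A moderate cohort with every exposure effect zero."""
    from mpepi import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_cases=400, effect_spec={}, missingness_rate=0.0, seed=101)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def effect_cohort():
    """A cohort generated under the default (study-patterned) SNP effects."""
    from mpepi import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_cases=1500, missingness_rate=0.0, seed=202)
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
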