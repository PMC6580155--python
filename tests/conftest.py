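import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from propcontest import ContestSpec, default_config, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def spec():
    return ContestSpec()


@pytest.fixture(scope="session")
def default_cohort():
    """The calibrated 3 x 30 x 20 cohort at the package's default seed."""
    return generate_cohort(default_config())


@pytest.fixture(scope="session")
def small_cohort():
    """A small, fast cohort (3 x 6 x 5) for structural tests."""
    from dataclasses import replace

    cfg = replace(default_config(seed=7), participants_per_condition=6, periods=5)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
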