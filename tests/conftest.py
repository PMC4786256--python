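import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from lactospec import methods_cohort_fixture, table1_fixture
from lactospec.synthetic_data import SimulationConfig, generate


@pytest.fixture(scope="session")
def cohort_samples():
    """The built-in 50-woman study cohort."""
    return methods_cohort_fixture()


@pytest.fixture(scope="session")
def table1_proteins():
    """The 18 published species-specific proteins."""
    return table1_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A default-configuration synthetic dataset (50 samples, 40 proteins)."""
    return generate(SimulationConfig(seed=7))
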