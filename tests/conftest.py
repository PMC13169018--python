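import pytest

from dietbrain import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort at the default calibration, shared across tests."""
    return generate_cohort(GeneratorConfig(n_dyads=2000, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """A large cohort for moment checks (score mean/SD, correlations)."""
    return generate_cohort(GeneratorConfig(n_dyads=20000, seed=5))
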