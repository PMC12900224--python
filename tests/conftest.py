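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


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture(scope="session")
def small_registry():
    """A modest synthetic registry shared by read-only tests."""
    from dcdliver.registry import GeneratorConfig, generate_registry

    config = GeneratorConfig(n_donors=2500, seed=42)
    donors, transplants, truth = generate_registry(config)
    return config, donors, transplants, truth
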