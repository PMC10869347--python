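import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pwcmr import SyntheticConfig, simulate_study

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One default synthetic study shared across read-only tests."""
    return simulate_study(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def small_study():
    """Lean study without mediator/null candidate for cheap checks."""
    cfg = SyntheticConfig(
        seed=5,
        n_snps_per_cluster=(20, 20),
        alpha_k=(-0.1, -0.1),
        confounder_cluster=None,
        include_mediator=False,
        include_null_candidate=False,
        traits_per_cluster=3,
        n_noise_traits=2,
    )
    return simulate_study(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
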