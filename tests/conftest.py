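import pytest
from hypothesis import HealthCheck, settings

from ldnekit.simulate import DemographyConfig, simulate_wright_fisher

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_sim():
    """A small drifted cohort reused by several suites: 3 x 5 Mb chromosomes."""
    cfg = DemographyConfig(
        ne_schedule=((0, 60),),
        n_generations=120,
        n_chromosomes=3,
        chromosome_length_bp=5_000_000,
        n_markers_per_chromosome=80,
        n_samples=40,
        missing_rate=0.03,
        seed=11,
    )
    return simulate_wright_fisher(cfg)
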