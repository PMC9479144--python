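import pytest
from hypothesis import HealthCheck, settings

from mitescan.simulate import SimulationConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Error-free, moderate-coverage conditions for fast exact checks."""
    return SimulationConfig(
        n_chromosomes=2,
        chrom_length=80_000,
        n_genes=6,
        n_insertions=8,
        coverage_per_site=60,
        error_rate=0.0,
        n_deg_up=2,
        n_deg_down=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
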