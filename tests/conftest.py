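import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from sexmark import (  # noqa: E402
    GenomeModel,
    ReadSimConfig,
    simulate_genomes,
    simulate_pool_reads,
)


@pytest.fixture(scope="session")
def small_genomes():
    """A compact XX/XY genome set shared by the slower integration tests."""
    model = GenomeModel(
        autosome_length=20_000, x_region_length=4_000, y_msr_length=4_000, seed=7
    )
    return simulate_genomes(model)


@pytest.fixture(scope="session")
def small_pools(small_genomes):
    """Error-free 20x pools over the small genome set."""
    male = simulate_pool_reads(
        small_genomes.male,
        ReadSimConfig(coverage=20, error_rate=0.0, seed=11),
        small_genomes.male_weights,
        name_prefix="male_",
    )
    female = simulate_pool_reads(
        small_genomes.female,
        ReadSimConfig(coverage=20, error_rate=0.0, seed=12),
        small_genomes.female_weights,
        name_prefix="female_",
    )
    return male, female
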