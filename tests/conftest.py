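import pytest
from hypothesis import HealthCheck, settings

from varrep.synth import ProteomeConfig, SamplingSpec, generate_proteome, \
    generate_variant_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def universe():
    """Default small synthetic universe: 200 proteins, seed 7."""
    return generate_proteome(ProteomeConfig(protein_count=200, seed=7))


@pytest.fixture(scope="session")
def large_universe():
    """Bigger universe for power-hungry distribution properties."""
    return generate_proteome(ProteomeConfig(protein_count=500, seed=42))


@pytest.fixture(scope="session")
def uniform_records(universe):
    return generate_variant_dataset(
        universe,
        SamplingSpec(mode="uniform", n_variants=3000, seed=3,
                     dataset_label="uniform"),
    )
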