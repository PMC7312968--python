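import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from idrpipe.simulate import (
    GOModel,
    PlantedTerm,
    SimulationConfig,
    make_tiny_worked_example,
    simulate_proteome,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A small paired-proteome simulation shared across read-back tests."""
    return SimulationConfig(
        seed=42,
        n_proteins=(100, 100),
        go=GOModel(n_terms=20, planted=(PlantedTerm("GO:0000001", "Camelus", 5.0),)),
        ambiguous_spike_rate=0.1,
    )


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_proteome(small_config, "Camelus")


@pytest.fixture(scope="session")
def fixture_dir(small_sim, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    from idrpipe.simulate import write_fixture_set

    files = write_fixture_set(small_sim, out, dialects=("disopred3", "iupred", "generic_tsv"))
    return files


@pytest.fixture(scope="session")
def worked_example():
    return make_tiny_worked_example()
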