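import pytest

from hicrepeats.simulate import (
    SimulationConfig,
    build_variant_library,
    generate_allele,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7, variant_library_size=12)


@pytest.fixture(scope="session")
def library(sim_config):
    return build_variant_library(sim_config)


@pytest.fixture()
def clean_allele(sim_config, library):
    """11 distinct planted variants, 500-nt flanks, no mutations."""
    return generate_allele(
        sim_config, list(range(1, 12)), allele_id="clean11", library=library
    )
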