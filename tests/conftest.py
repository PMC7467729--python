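import pytest

from foldback_forge.config import SimConfig
from foldback_forge.genome import build_toy_genome, planted_hairpin_sites
from foldback_forge.mapping import ReferenceIndex


@pytest.fixture(scope="session")
def config() -> SimConfig:
    return SimConfig(master_seed=1)


@pytest.fixture(scope="session")
def reference(config):
    return build_toy_genome(config)


@pytest.fixture(scope="session")
def ref_index(reference):
    return ReferenceIndex(reference)


@pytest.fixture(scope="session")
def planted_sites(reference, config):
    return planted_hairpin_sites(reference, config)
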