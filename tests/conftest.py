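import numpy as np
import pytest

from paleosoar.morphology import Environment, registry, expand_pelagornis_configs


@pytest.fixture(scope="session")
def env():
    return Environment()


@pytest.fixture(scope="session")
def reg():
    return registry(include_pelagornis=True)


@pytest.fixture(scope="session")
def albatross(reg):
    return reg["wandering_albatross"]


@pytest.fixture(scope="session")
def quetzalcoatlus(reg):
    return reg["quetzalcoatlus"]


@pytest.fixture(scope="session")
def extinct_configs(reg):
    """All 28 extinct-taxon configurations of the thermal comparison."""
    return expand_pelagornis_configs() + [
        reg[n]
        for n in (
            "argentavis_magnificens",
            "pteranodon_witton",
            "pteranodon_henderson",
            "quetzalcoatlus",
        )
    ]
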