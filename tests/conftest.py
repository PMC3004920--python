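import numpy as np
import pytest

from duxevo.family_sim import FamilySimConfig, simulate_family
from duxevo.pipeline_cli import (DEFAULT_EVENTS, DEFAULT_FAMILIES,
                                 DEFAULT_SPECIES_TREE)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20_260_922)


@pytest.fixture(scope="session")
def benchmark_sim():
    """The default 6-species / 4-family benchmark simulation."""
    cfg = FamilySimConfig(species_tree=DEFAULT_SPECIES_TREE,
                          families=list(DEFAULT_FAMILIES),
                          events=list(DEFAULT_EVENTS), seed=11)
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """A minimal 3-species, single intact family."""
    tree = "((sp1:0.05,sp2:0.05):0.03,sp3:0.08);"
    cfg = FamilySimConfig(species_tree=tree, families=["DUX"], seed=5)
    return simulate_family(cfg)
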