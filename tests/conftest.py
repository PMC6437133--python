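import pytest
from hypothesis import settings

from netmpl.generate import GeneratorConfig, random_level1_network
from netmpl.io import read_enewick, read_newick_tree
from netmpl.reduction import build_instance, cubic_fixtures, derive_gadget

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

SINGLE_GALL = "((a,(b)#H1),(#H1,c));"


@pytest.fixture
def single_gall_net():
    return read_enewick(SINGLE_GALL)


@pytest.fixture
def cherry_tree():
    return read_newick_tree("(x,y);")


@pytest.fixture(scope="session")
def gadget():
    return derive_gadget()


@pytest.fixture(scope="session")
def fixtures_cubic():
    return cubic_fixtures()


@pytest.fixture(scope="session")
def k4_instance(fixtures_cubic):
    return build_instance(fixtures_cubic["K4"])


def random_net(seed, n=6, r=1, probs=None):
    cfg = GeneratorConfig(seed=seed, n_taxa=n, n_reticulations=r, prob_range=probs)
    return random_level1_network(cfg)
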