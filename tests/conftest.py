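import pytest

from bindnet import build_network
from bindnet.simulate import NetworkSimSpec, simulate_network


@pytest.fixture
def toy_network():
    """Three edges, two TFs, two promoters in pathways A / A+B."""
    return build_network(
        [("T1", "P1"), ("T1", "P2"), ("T2", "P1")],
        pathway_table={"P1": {"A"}, "P2": {"B"}},
    )


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic quarter-scale synthetic network (shared, read-only)."""
    return simulate_network(NetworkSimSpec(seed=7))
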