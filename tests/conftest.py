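import pytest

from walkset.io import GeneSet, Network, map_set
from walkset.synth import SyntheticSpec, generate


@pytest.fixture
def path_net() -> Network:
    """A - B - C path with unit weights."""
    return Network.from_edges([("A", "B", 1.0), ("B", "C", 1.0)])


@pytest.fixture
def two_node_net() -> Network:
    return Network.from_edges([("A", "B", 1.0)])


@pytest.fixture
def small_bundle():
    """Small synthetic bundle with one planted pathway (fast to score)."""
    spec = SyntheticSpec(
        n_nodes=120,
        attachment=2,
        target_size=10,
        pathway_sizes=[12] * 4,
        planted=[("PW1", 0.5)],
        target_overlap=[("PW2", 4), ("PW3", 2)],
        seed=7,
    )
    return generate(spec)


def mapped(members: set[str], net: Network, set_id: str = "S") -> "object":
    gs = GeneSet(set_id=set_id, name=set_id, members=frozenset(members))
    return map_set(gs, net, min_mapped=1)
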