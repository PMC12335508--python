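import networkx as nx
import pytest

from topodrug import reference
from topodrug.molgraph import MolecularGraph, parse_edgelist


@pytest.fixture
def path3() -> MolecularGraph:
    return parse_edgelist("1 2\n2 3", name="path3")


@pytest.fixture
def star3() -> MolecularGraph:
    return parse_edgelist("1 2\n1 3\n1 4", name="star3")


@pytest.fixture
def single_edge() -> MolecularGraph:
    return parse_edgelist("1 2", name="k2")


@pytest.fixture(scope="session")
def drug_graphs() -> dict[str, MolecularGraph]:
    return reference.drug_graphs()


@pytest.fixture(scope="session")
def published_indices():
    return reference.published_indices()


@pytest.fixture(scope="session")
def property_table():
    return reference.property_table()


def random_graph(seed: int, n: int = 12):
    """Session-local helper: a seeded connected cap-4 graph via the package generator."""
    from topodrug.synthetic_data import GeneratorConfig, random_molecular_graph

    return random_molecular_graph(GeneratorConfig(seed=seed, n_vertices=n))


@pytest.fixture
def permute():
    def _permute(g: MolecularGraph, seed: int = 0) -> MolecularGraph:
        import random

        rng = random.Random(seed)
        nodes = list(g.graph.nodes)
        shuffled = nodes[:]
        rng.shuffle(shuffled)
        mapping = dict(zip(nodes, shuffled))
        return MolecularGraph(name=g.name, graph=nx.relabel_nodes(g.graph, mapping))

    return _permute
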