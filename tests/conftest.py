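import pytest

from protokg.graph_store import default_schema
from protokg.synthetic_fixtures import (KGSpec, SimSpec, generate_knowledge_graph,
                                        simulate_proteomics)


@pytest.fixture(scope="session")
def schema():
    return default_schema()


@pytest.fixture(scope="session")
def toy_kg():
    """Small seeded knowledge graph plus its ground-truth tables."""
    return generate_knowledge_graph(KGSpec(seed=7))


@pytest.fixture(scope="session")
def sim_experiment():
    """Simulated two-group experiment (60 features) with planted effects."""
    return simulate_proteomics(SimSpec(seed=11, n_features=60))


def write_graph_files(tmp_path, nodes_rows, edges_rows,
                      node_header="ID\tLABEL", edge_header="START_ID\tEND_ID\tTYPE"):
    nodes = tmp_path / "nodes.tsv"
    edges = tmp_path / "edges.tsv"
    nodes.write_text("\n".join([node_header] + nodes_rows) + "\n")
    edges.write_text("\n".join([edge_header] + edges_rows) + "\n")
    return nodes, edges
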