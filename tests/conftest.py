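import networkx as nx
import numpy as np
import pandas as pd
import pytest

from nbbd import GeneratorParams, OTUTable, make_benchmark


def named(graph: nx.Graph, prefix: str = "v") -> nx.Graph:
    """Relabel integer nodes to deterministic string IDs."""
    return nx.relabel_nodes(graph, {i: f"{prefix}{i}" for i in graph.nodes})


@pytest.fixture
def path3() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c")])


@pytest.fixture
def triangle() -> nx.Graph:
    return nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])


@pytest.fixture
def star5() -> nx.Graph:
    """Star: center c plus four leaves."""
    return nx.Graph([("c", "l1"), ("c", "l2"), ("c", "l3"), ("c", "l4")])


@pytest.fixture
def small_table() -> OTUTable:
    data = pd.DataFrame(
        [[2.0, 2.0, 4.0], [1.0, 3.0, 6.0], [5.0, 0.0, 5.0], [4.0, 4.0, 2.0]],
        index=["s1", "s2", "s3", "s4"],
        columns=["tA", "tB", "tC"],
    )
    labels = pd.Series(["x", "x", "y", "y"], index=data.index)
    return OTUTable(data, labels=labels)


@pytest.fixture(scope="session")
def default_benchmark():
    """One default-parameter benchmark shared across tests."""
    return make_benchmark(GeneratorParams(seed=7))


@pytest.fixture(scope="session")
def atlas_graphs():
    """All connected graphs with 2..7 nodes, one per isomorphism class."""
    from networkx.generators.atlas import graph_atlas_g

    out = []
    for g in graph_atlas_g():
        if g.number_of_nodes() >= 2 and nx.is_connected(g):
            out.append(named(g))
    return out


def labeled_random_table(n_samples=40, n_taxa=12, seed=0, separating=None):
    """Random count table with binary labels; optionally one taxon whose
    abundance perfectly separates the classes."""
    rng = np.random.default_rng(seed)
    counts = rng.integers(0, 50, size=(n_samples, n_taxa)).astype(float)
    labels = np.array(["g1"] * (n_samples // 2) + ["g2"] * (n_samples - n_samples // 2))
    taxa = [f"t{i:02d}" for i in range(n_taxa)]
    df = pd.DataFrame(counts, index=[f"s{i:03d}" for i in range(n_samples)], columns=taxa)
    if separating is not None:
        df[separating] = np.where(labels == "g1", 1.0, 100.0)
    return OTUTable(df, labels=pd.Series(labels, index=df.index))
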