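"""Node Topological Property Scoring (NTPS).

Given one network per phenotype, each shared node v is scored by the absolute
difference of a topological property between the two graphs:

    score_P(v) = | f_P(v, G_a) - f_P(v, G_b) |

Six unweighted properties are supported: betweenness centrality (``btw``,
unnormalised pair sums), closeness centrality (``cls``, reachable-set
variant), average neighbour degree (``and``), clustering coefficient
(``cc``), node clique number (``ncn``) and core number (``cn``). A node with
a large score interacts differently with the rest of the community in the two
phenotypes, which is the working definition of a network biomarker here.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = ["PROPERTIES", "compute_property", "ntps_score", "ntps_score_table"]

PROPERTIES = ("btw", "cls", "and", "cc", "ncn", "cn")


def compute_property(g: nx.Graph, property_name: str) -> dict[str, float]:
    """One topological property for every node of ``g``.

    Degenerate nodes (isolated, or degree < 2 for the clustering coefficient)
    get value 0 so that cross-network differences stay finite. Edge weights
    are ignored throughout.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if property_name == "btw":
        # unnormalised; networkx counts each unordered pair once
        return dict(nx.betweenness_centrality(g, normalized=False))
    if property_name == "cls":
        # (n_reachable - 1) / sum of distances; isolated nodes -> 0
        return dict(nx.closeness_centrality(g, wf_improved=False))
    if property_name == "and":
        return dict(nx.average_neighbor_degree(g))
    if property_name == "cc":
        return dict(nx.clustering(g))
    if property_name == "ncn":
        return {v: float(k) for v, k in nx.node_clique_number(g).items()}
    if property_name == "cn":
        return {v: float(k) for v, k in nx.core_number(g).items()}
    raise ValueError(f"unknown property: {property_name!r}; choose from {PROPERTIES}")


def ntps_score(g_a: nx.Graph, g_b: nx.Graph, property_name: str) -> dict[str, float]:
    """Absolute property difference on the shared node set."""
    shared = set(g_a.nodes) & set(g_b.nodes)
    if not shared:
        raise ValueError(
            f"graphs share no nodes ({g_a.number_of_nodes()} vs "
            f"{g_b.number_of_nodes()} nodes)"
        )
    f_a = compute_property(g_a, property_name)
    f_b = compute_property(g_b, property_name)
    return {v: abs(f_a[v] - f_b[v]) for v in sorted(shared)}


def ntps_score_table(g_a: nx.Graph, g_b: nx.Graph, property_name: str) -> pd.DataFrame:
    """Per-node table with both property values and the NTPS score."""
    shared = sorted(set(g_a.nodes) & set(g_b.nodes))
    if not shared:
        raise ValueError("graphs share no nodes")
    f_a = compute_property(g_a, property_name)
    f_b = compute_property(g_b, property_name)
    return pd.DataFrame({
        "taxon_id": shared,
        "property": property_name,
        "value_a": [f_a[v] for v in shared],
        "value_b": [f_b[v] for v in shared],
        "score": [abs(f_a[v] - f_b[v]) for v in shared],
    }).set_index("taxon_id")
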