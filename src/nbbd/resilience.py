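"""Node-based resilience measures and Critical Attack Set Scoring (CASS).

An *attack set* S is a node subset whose removal fragments the graph. Three
measures grade candidate sets, with C_max the order of the largest component
of G - S and omega the number of components of G - S:

    VAT(S)       = |S| / (|V - S| - C_max + 1)       (S nonempty)
    integrity(S) = |S| + C_max
    tenacity(S)  = (|S| + C_max) / omega

Each measure's value on a graph is the minimum over admissible S. The greedy
betweenness heuristic (Greedy-BC) removes the currently most central node one
at a time; evaluating a measure on every prefix of that ordering and keeping
the minimising prefix approximates the optimum, and because all three
measures share one ordering the attack sets nest: S_VAT <= S_I <= S_T.

CASS selects biomarkers as the intersection of the two phenotype networks'
attack sets; the number of selected features is therefore data-driven rather
than a user parameter.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["MEASURES", "AttackSetResult", "greedy_bc_ordering", "measure_value",
           "optimize_measure", "brute_force_measure", "cass_select",
           "residual_components"]

MEASURES = ("vat", "integrity", "tenacity")


@dataclass
class AttackSetResult:
    """Outcome of minimising one resilience measure over greedy prefixes."""

    measure: str
    attack_set: set[str]
    value: float
    ordering: list[str]
    profile: list[tuple[int, float]]  # (prefix length, measure value)

    def components_after_removal(self, g: nx.Graph) -> list[set[str]]:
        """Connected components of G - attack_set, for inspection."""
        return residual_components(g, self.attack_set)


def residual_components(g: nx.Graph, s: set) -> list[set[str]]:
    rest = g.subgraph(set(g.nodes) - set(s))
    return [set(c) for c in nx.connected_components(rest)]


def _check_measure(measure: str) -> str:
    m = measure.lower()
    if m not in MEASURES:
        raise ValueError(f"unknown measure: {measure!r}; choose from {MEASURES}")
    return m


def measure_value(g: nx.Graph, s, measure: str) -> float:
    """Evaluate one resilience measure for the attack set ``s`` on ``g``."""
    m = _check_measure(measure)
    s = set(s)
    extra = s - set(g.nodes)
    if extra:
        raise ValueError(f"attack set contains nodes outside the graph: {sorted(extra)}")
    n = g.number_of_nodes()
    comps = residual_components(g, s)
    c_max = max((len(c) for c in comps), default=0)
    omega = len(comps) if comps else 1  # S = V: treat omega as 1
    if m == "vat":
        if not s:
            raise ValueError("VAT is undefined for the empty attack set")
        return len(s) / ((n - len(s)) - c_max + 1)
    if m == "integrity":
        return float(len(s) + c_max)
    return (len(s) + c_max) / omega


def greedy_bc_ordering(g: nx.Graph) -> list[str]:
    """Node-removal ordering by repeated highest betweenness.

    Betweenness is recomputed on the whole residual graph after every removal
    (per-component shortest paths when it disconnects); ties break
    lexicographically on node ID. If ``g`` is disconnected, its largest
    component is used (logged).
    """
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if not nx.is_connected(g):
        largest = max(nx.connected_components(g), key=lambda c: (len(c), sorted(c)))
        logger.info("graph disconnected; Greedy-BC runs on the largest component "
                    "(%d of %d nodes)", len(largest), g.number_of_nodes())
        g = g.subgraph(largest)
    residual = nx.Graph(g)
    ordering: list[str] = []
    while residual.number_of_nodes() > 0:
        bc = nx.betweenness_centrality(residual, normalized=False)
        pick = min(bc, key=lambda v: (-bc[v], str(v)))
        ordering.append(pick)
        residual.remove_node(pick)
    return ordering


def optimize_measure(
    g: nx.Graph, measure: str, ordering: list[str] | None = None
) -> AttackSetResult:
    """Minimise a measure over prefixes of the Greedy-BC ordering.

    Prefix sizes run 1..n-1 for VAT and 0..n-1 for integrity/tenacity; on a
    tie the smallest prefix wins. Passing a precomputed ``ordering`` lets the
    three measures share one ordering (which guarantees the nesting
    S_VAT <= S_I <= S_T).
    """
    m = _check_measure(measure)
    if g.number_of_nodes() < 2:
        raise ValueError("graph must have at least 2 nodes")
    if ordering is None:
        ordering = greedy_bc_ordering(g)
    # restrict evaluation to the component the ordering covers
    sub = g.subgraph(ordering)
    start = 1 if m == "vat" else 0
    profile = []
    for size in range(start, len(ordering)):
        val = measure_value(sub, ordering[:size], m)
        profile.append((size, val))
    best_size, best_val = min(profile, key=lambda p: (p[1], p[0]))
    return AttackSetResult(
        measure=m,
        attack_set=set(ordering[:best_size]),
        value=best_val,
        ordering=list(ordering),
        profile=profile,
    )


def optimize_all(g: nx.Graph) -> dict[str, AttackSetResult]:
    """All three measures from one shared Greedy-BC ordering."""
    ordering = greedy_bc_ordering(g)
    return {m: optimize_measure(g, m, ordering=ordering) for m in MEASURES}


def brute_force_measure(g: nx.Graph, measure: str) -> tuple[float, set[str]]:
    """Exhaustive minimum over admissible proper subsets (test oracle).

    Enforced for graphs of at most 16 nodes. Ties resolve to the smallest
    set, then lexicographically.
    """
    m = _check_measure(measure)
    nodes = sorted(g.nodes, key=str)
    n = len(nodes)
    if n > 16:
        raise ValueError("brute force is limited to 16 nodes")
    if n < 2:
        raise ValueError("graph must have at least 2 nodes")
    index = {v: i for i, v in enumerate(nodes)}
    adj = [0] * n
    for u, v in g.edges():
        adj[index[u]] |= 1 << index[v]
        adj[index[v]] |= 1 << index[u]
    best: tuple[float, int, tuple] | None = None
    min_size = 1 if m == "vat" else 0
    for size in range(min_size, n):
        for combo in itertools.combinations(range(n), size):
            removed = 0
            for i in combo:
                removed |= 1 << i
            # component sizes of the residual graph via bitmask BFS
            remaining = ((1 << n) - 1) & ~removed
            c_max, omega = 0, 0
            todo = remaining
            while todo:
                seed_bit = todo & -todo
                comp = seed_bit
                frontier = seed_bit
                while frontier:
                    nxt = 0
                    f = frontier
                    while f:
                        b = f & -f
                        f ^= b
                        nxt |= adj[b.bit_length() - 1]
                    frontier = nxt & remaining & ~comp
                    comp |= frontier
                size_c = comp.bit_count()
                omega += 1
                c_max = max(c_max, size_c)
                todo &= ~comp
            k = len(combo)
            if m == "vat":
                val = k / ((n - k) - c_max + 1)
            elif m == "integrity":
                val = float(k + c_max)
            else:
                val = (k + c_max) / (omega if omega else 1)
            names = tuple(nodes[i] for i in combo)
            key = (val, k, names)
            if best is None or key < best:
                best = key
    assert best is not None
    return best[0], set(best[2])


def cass_select(g_a: nx.Graph, g_b: nx.Graph, measure: str) -> set[str]:
    """Taxa shared by the critical attack sets of the two phenotype networks.

    May be empty (logged): with very different networks the two attack sets
    need not overlap, in which case no features are selected.
    """
    m = _check_measure(measure)
    s_a = optimize_measure(g_a, m).attack_set
    s_b = optimize_measure(g_b, m).attack_set
    shared = s_a & s_b
    if not shared:
        logger.warning("CASS(%s): attack sets are disjoint; no features selected", m)
    return shared
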