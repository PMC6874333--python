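"""Independent brute-force references for graph quantities.

These deliberately avoid networkx algorithms (plain BFS, subset enumeration,
union-find) so they can serve as double-entry checks for the package's
property and resilience computations on small graphs.
"""

from itertools import combinations


def adjacency(g):
    return {v: set(g.neighbors(v)) for v in g.nodes}


def bfs_distances(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def shortest_path_counts(adj, source):
    """(distance, path count) to every reachable node, by BFS layering."""
    dist = {source: 0}
    count = {source: 1}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    count[w] = 0
                    nxt.append(w)
                if dist[w] == dist[u] + 1:
                    count[w] += count[u]
        frontier = nxt
    return dist, count


def betweenness(g):
    """Unnormalised betweenness via explicit path enumeration over pairs."""
    adj = adjacency(g)
    nodes = sorted(adj)
    all_paths = {}
    for s in nodes:
        all_paths[s] = shortest_path_counts(adj, s)
    btw = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        dist_s, cnt_s = all_paths[s]
        if t not in dist_s:
            continue
        d = dist_s[t]
        sigma = cnt_s[t]
        dist_t, cnt_t = all_paths[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == d:
                btw[v] += cnt_s[v] * cnt_t[v] / sigma
    return btw


def closeness(g):
    adj = adjacency(g)
    out = {}
    for v in adj:
        dist = bfs_distances(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def average_neighbor_degree(g):
    adj = adjacency(g)
    return {
        v: (sum(len(adj[u]) for u in adj[v]) / len(adj[v]) if adj[v] else 0.0)
        for v in adj
    }


def clustering_coefficient(g):
    adj = adjacency(g)
    out = {}
    for v in adj:
        k = len(adj[v])
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(1 for u, w in combinations(sorted(adj[v]), 2) if w in adj[u])
        out[v] = 2 * links / (k * (k - 1))
    return out


def node_clique_number(g):
    """Largest clique containing each node, by subset enumeration."""
    adj = adjacency(g)
    nodes = sorted(adj)
    out = {v: 1 for v in nodes}
    for size in range(2, len(nodes) + 1):
        for combo in combinations(nodes, size):
            if all(w in adj[u] for u, w in combinations(combo, 2)):
                for v in combo:
                    out[v] = max(out[v], size)
    return out


def core_number(g):
    """Iterative shell peeling."""
    adj = {v: set(ns) for v, ns in adjacency(g).items()}
    out = {}
    k = 0
    while adj:
        while True:
            peel = [v for v, ns in adj.items() if len(ns) <= k]
            if not peel:
                break
            for v in peel:
                out[v] = k
                for u in adj[v]:
                    adj[u].discard(v)
                del adj[v]
        k += 1
    return out


def component_stats(g, removed):
    """(largest component size, component count) of g minus ``removed``,
    via union-find."""
    removed = set(removed)
    nodes = [v for v in g.nodes if v not in removed]
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for u, w in g.edges():
        if u in parent and w in parent:
            ru, rw = find(u), find(w)
            if ru != rw:
                parent[ru] = rw
    sizes = {}
    for v in nodes:
        r = find(v)
        sizes[r] = sizes.get(r, 0) + 1
    if not sizes:
        return 0, 0
    return max(sizes.values()), len(sizes)


def resilience_value(g, s, measure):
    """The three resilience formulas from the union-find component stats."""
    n = g.number_of_nodes()
    c_max, omega = component_stats(g, s)
    k = len(s)
    if measure == "vat":
        return k / ((n - k) - c_max + 1)
    if measure == "integrity":
        return float(k + c_max)
    return (k + c_max) / (omega if omega else 1)


def brute_force_minimum(g, measure):
    """Exhaustive minimum of a resilience measure over proper subsets."""
    nodes = sorted(g.nodes)
    best = None
    min_size = 1 if measure == "vat" else 0
    for size in range(min_size, len(nodes)):
        for combo in combinations(nodes, size):
            val = resilience_value(g, set(combo), measure)
            if best is None or (val, size, combo) < best:
                best = (val, size, combo)
    return best[0], set(best[2])
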