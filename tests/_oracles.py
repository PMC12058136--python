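"""Independent brute-force oracles for small-graph network metrics.

Everything here enumerates explicitly (simple paths, set partitions) and
shares no code with the package's implementations.
"""

from itertools import permutations

import numpy as np


def all_simple_paths(adj, s, t, nodes):
    """All simple paths s..t as node tuples; adj is {node: set(neighbors)}."""
    paths = []
    inner = [v for v in nodes if v not in (s, t)]
    for k in range(len(inner) + 1):
        for mid in permutations(inner, k):
            seq = (s, *mid, t)
            if all(seq[i + 1] in adj[seq[i]] for i in range(len(seq) - 1)):
                paths.append(seq)
    return paths


def shortest_path_census(adj, nodes):
    """For each ordered pair: (distance, count of geodesics, per-node pass counts).

    Unit edge lengths. Distance is inf for unreachable pairs.
    """
    census = {}
    for s in nodes:
        for t in nodes:
            if s == t:
                continue
            paths = all_simple_paths(adj, s, t, nodes)
            if not paths:
                census[(s, t)] = (np.inf, 0, {})
                continue
            dmin = min(len(p) - 1 for p in paths)
            geos = [p for p in paths if len(p) - 1 == dmin]
            through = {}
            for p in geos:
                for v in p[1:-1]:
                    through[v] = through.get(v, 0) + 1
            census[(s, t)] = (dmin, len(geos), through)
    return census


def brute_betweenness(adj, nodes):
    census = shortest_path_census(adj, nodes)
    bt = {v: 0.0 for v in nodes}
    node_list = list(nodes)
    for i, s in enumerate(node_list):
        for t in node_list[i + 1:]:
            d, sigma, through = census[(s, t)]
            if sigma == 0:
                continue
            for v, cnt in through.items():
                bt[v] += cnt / sigma
    return bt


def brute_closeness(adj, nodes):
    """(reachable - 1) / sum of distances to reachable nodes; isolates 0."""
    census = shortest_path_census(adj, nodes)
    out = {}
    for s in nodes:
        ds = [census[(s, t)][0] for t in nodes if t != s]
        finite = [d for d in ds if np.isfinite(d)]
        out[s] = len(finite) / sum(finite) if finite else 0.0
    return out


def pagerank_residual(pr, adj_weighted, nodes, alpha=0.85):
    """Max residual of the PageRank defining equations with uniform
    redistribution of dangling mass."""
    N = len(nodes)
    out_w = {u: sum(adj_weighted[u].values()) for u in nodes}
    dangling = sum(pr[u] for u in nodes if out_w[u] == 0)
    worst = 0.0
    for i in nodes:
        inflow = sum(
            pr[j] * adj_weighted[j][i] / out_w[j]
            for j in nodes
            if out_w[j] > 0 and i in adj_weighted[j]
        )
        rhs = (1 - alpha) / N + alpha * (inflow + dangling / N)
        worst = max(worst, abs(pr[i] - rhs))
    return worst


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [[first] + part[k]] + part[k + 1:]
        yield part + [[first]]


def brute_modularity(edges_abs, partition):
    """Direct formula on a list of ((u,v), weight) with weights >= 0."""
    m = sum(w for _, w in edges_abs)
    if m == 0:
        return 0.0
    label = {}
    for k, group in enumerate(partition):
        for v in group:
            label[v] = k
    q = 0.0
    labels = set(label.values())
    for l in labels:
        w_in = sum(w for (u, v), w in edges_abs if label[u] == l and label[v] == l)
        d = sum(
            w * ((label[u] == l) + (label[v] == l)) for (u, v), w in edges_abs
        )
        q += w_in / m - (d / (2 * m)) ** 2
    return q
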