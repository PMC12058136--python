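"""Community detection and centrality metrics for disease networks.

Communities ("multimorbidity patterns") come from greedy agglomerative
modularity maximization (CNM fast-greedy): start from singletons and
repeatedly merge the community pair with the largest modularity gain until
no merge improves Q. Ties are broken toward the lexicographically smallest
community-id pair, so runs are bit-reproducible.

Centralities are the six standard measures used to nominate bridging
diseases: degree (incident edge count), closeness, betweenness, PageRank,
eigenvector centrality and the HITS hub score. Signed association weights
enter every metric through their absolute value; shortest-path metrics use
lengths 1/|weight| (strong association = short distance) in the default
weighted mode.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .network import PairwiseNetwork

__all__ = [
    "CommunityPartition",
    "detect_communities",
    "modularity",
    "compute_centralities",
    "rank_bridges",
]


@dataclass
class CommunityPartition:
    assignment: dict            # disease code -> community id (0..k-1)
    Q: float
    merge_history: list = field(default_factory=list)

    def communities(self) -> dict:
        out: dict[int, list] = {}
        for code, cid in self.assignment.items():
            out.setdefault(cid, []).append(code)
        return {cid: out[cid] for cid in sorted(out)}

    def community_of(self, code: str) -> int:
        return self.assignment[code]

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def to_json(self, path) -> None:
        payload = {str(cid): codes for cid, codes in self.communities().items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"Q": self.Q, "communities": payload}, fh, indent=1)


def _abs_weights(net: PairwiseNetwork):
    return {pair: abs(w) for pair, (w, _) in net.edges.items()}


def modularity(net: PairwiseNetwork, partition) -> float:
    """Weighted modularity Q = sum_c [ W_c/m - (d_c/(2m))^2 ].

    ``partition`` is a mapping code -> community label or an iterable of
    node sets. ``W_c`` is total within-community edge weight (each edge
    once), ``d_c`` the summed weighted degrees, ``m`` the total edge
    weight; weights are absolute. An edgeless network has Q defined as 0.
    """
    if isinstance(partition, dict):
        label_of = dict(partition)
    else:
        label_of = {}
        for k, group in enumerate(partition):
            for node in group:
                label_of[node] = k
    missing = set(net.nodes) - set(label_of)
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(missing)}")
    weights = _abs_weights(net)
    m = sum(weights.values())
    if m == 0:
        warnings.warn("edgeless network: modularity defined as 0")
        return 0.0
    labels = set(label_of[n] for n in net.nodes)
    W_c = {l: 0.0 for l in labels}
    d_c = {l: 0.0 for l in labels}
    for (u, v), w in weights.items():
        d_c[label_of[u]] += w
        d_c[label_of[v]] += w
        if label_of[u] == label_of[v]:
            W_c[label_of[u]] += w
    return sum(W_c[l] / m - (d_c[l] / (2 * m)) ** 2 for l in labels)


def detect_communities(net: PairwiseNetwork) -> CommunityPartition:
    """CNM fast-greedy modularity maximization on absolute edge weights.

    Deterministic: community ids are the smallest member's catalog index,
    and among merges of maximal gain the lexicographically smallest id pair
    is taken. Isolated nodes end as singleton communities.
    """
    nodes = list(net.nodes)
    if not nodes:
        raise ValueError("network has no nodes")
    index = {c: i for i, c in enumerate(nodes)}
    weights = _abs_weights(net)
    m = sum(weights.values())
    members = {i: {c} for i, c in enumerate(nodes)}
    history: list[tuple] = []
    if m > 0:
        deg = {i: 0.0 for i in members}
        between: dict[tuple, float] = {}
        for (u, v), w in weights.items():
            iu, iv = index[u], index[v]
            deg[iu] += w
            deg[iv] += w
            pair = (min(iu, iv), max(iu, iv))
            between[pair] = between.get(pair, 0.0) + w
        within = {i: 0.0 for i in members}
        while True:
            best_gain = 0.0
            best_pair = None
            for (a, b), e_ab in between.items():
                gain = e_ab / m - deg[a] * deg[b] / (2.0 * m * m)
                if gain > best_gain + 1e-15 or (
                    best_pair is not None
                    and abs(gain - best_gain) <= 1e-15
                    and (a, b) < best_pair
                ):
                    best_gain = gain
                    best_pair = (a, b)
            if best_pair is None or best_gain <= 0.0:
                break
            a, b = best_pair
            members[a] |= members.pop(b)
            within[a] = within[a] + within.pop(b) + between.pop((a, b))
            deg[a] += deg.pop(b)
            new_between: dict[tuple, float] = {}
            for (x, y), w in between.items():
                x2 = a if x == b else x
                y2 = a if y == b else y
                pair = (min(x2, y2), max(x2, y2))
                new_between[pair] = new_between.get(pair, 0.0) + w
            between = new_between
            q_after = sum(
                within[i] / m - (deg[i] / (2 * m)) ** 2 for i in members
            )
            history.append((a, b, best_gain, q_after))
    # consecutive ids ordered by the smallest member's catalog position
    order = sorted(members.values(), key=lambda s: min(index[c] for c in s))
    assignment = {}
    for cid, group in enumerate(order):
        for code in group:
            assignment[code] = cid
    Q = modularity(net, assignment) if m > 0 else 0.0
    return CommunityPartition(assignment=assignment, Q=Q, merge_history=history)


# ---------------------------------------------------------------------------
# centralities


def _metric_graph(net: PairwiseNetwork, weighted: bool) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(net.nodes)
    for (u, v), (w, _) in net.edges.items():
        aw = abs(w) if weighted else 1.0
        g.add_edge(u, v, weight=aw, dist=1.0 / aw)
    return g


def _eigenvector_by_component(g: nx.Graph, nodes) -> tuple[dict, bool]:
    """Principal eigenvector of the absolute-weight adjacency, computed per
    connected component; only the component with the largest principal
    eigenvalue carries nonzero scores (others are 0). Returns the scores
    (max-normalized) and a flag marking a principal-eigenvalue tie between
    components."""
    scores = {n: 0.0 for n in nodes}
    best_lam = 0.0
    best_vec: dict | None = None
    tie = False
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) == 1:
            continue
        A = nx.to_numpy_array(g.subgraph(comp), nodelist=comp, weight="weight")
        # spectral shift keeps the iteration convergent on bipartite
        # components, where +/-lambda_max would otherwise make it oscillate
        shift = 1.0 + float(A.sum(axis=1).max())
        As = A + shift * np.eye(len(comp))
        v = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
        for _ in range(100000):
            v_new = As @ v
            v_new /= np.linalg.norm(v_new)
            if np.max(np.abs(v_new - v)) < 1e-13:
                v = v_new
                break
            v = v_new
        lam = float(v @ A @ v)
        if abs(lam - best_lam) <= 1e-9 * max(1.0, best_lam) and best_vec is not None:
            tie = True
        if lam > best_lam:
            best_lam = lam
            best_vec = dict(zip(comp, np.abs(v)))
    if best_vec:
        peak = max(best_vec.values())
        for n, val in best_vec.items():
            scores[n] = val / peak
    return scores, tie


def compute_centralities(
    net: PairwiseNetwork,
    weighted: bool = True,
    damping: float = 0.85,
    closeness_mode: str = "standard",
) -> pd.DataFrame:
    """Six-metric centrality table, one row per disease (catalog order).

    degree: incident edge count. closeness: component-restricted
    (reachable count)/(sum of shortest-path distances), 0 for isolates;
    ``closeness_mode='harmonic'`` switches to the harmonic mean variant.
    betweenness: Brandes on the same path lengths, unnormalized. pagerank:
    damping 0.85 on absolute weights, sums to 1. eigenvector and
    hub_score: max-normalized spectral scores (hub via HITS; equal to the
    authority score on undirected graphs).

    A tie in the principal eigenvalue across components is flagged in
    ``table.attrs['eigenvector_component_tie']``.
    """
    nodes = list(net.nodes)
    g = _metric_graph(net, weighted)
    degree = {n: net.degree(n) for n in nodes}
    if closeness_mode == "standard":
        closeness = nx.closeness_centrality(g, distance="dist", wf_improved=False)
    elif closeness_mode == "harmonic":
        raw = nx.harmonic_centrality(g, distance="dist")
        denom = max(len(nodes) - 1, 1)
        closeness = {n: raw[n] / denom for n in nodes}
    else:
        raise ValueError("closeness_mode must be 'standard' or 'harmonic'")
    betweenness = nx.betweenness_centrality(g, normalized=False, weight="dist")
    if net.n_edges == 0:
        pagerank = {n: 1.0 / len(nodes) for n in nodes}
        hub = {n: 0.0 for n in nodes}
        eigen = {n: 0.0 for n in nodes}
        tie = False
    else:
        pagerank = nx.pagerank(g, alpha=damping, weight="weight",
                               tol=1e-12, max_iter=2000)
        # uniform nstart pins the underlying svds start vector: without it
        # the result carries run-to-run noise at machine precision
        hub_raw, _auth = nx.hits(g, max_iter=10000, tol=1e-14,
                                 nstart={n: 1.0 for n in g})
        peak = max(abs(v) for v in hub_raw.values())
        hub = {n: abs(hub_raw[n]) / peak if peak > 0 else 0.0 for n in nodes}
        eigen, tie = _eigenvector_by_component(g, nodes)
    table = pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "pagerank": [pagerank[n] for n in nodes],
            "eigenvector": [eigen[n] for n in nodes],
            "hub_score": [hub[n] for n in nodes],
        },
        index=pd.Index(nodes, name="disease"),
    )
    table.attrs["eigenvector_component_tie"] = tie
    if tie:
        warnings.warn("principal eigenvalue tied across components; "
                      "eigenvector scores assigned to the first maximal component")
    return table


def rank_bridges(
    table: pd.DataFrame, metric: str = "betweenness", top_k: int | None = None
) -> pd.DataFrame:
    """Order diseases by a centrality metric to nominate bridging diseases.

    Descending by ``metric``; ties broken by degree (descending) then by
    catalog order. All six metrics stay in the returned table.
    """
    if table.empty:
        raise ValueError("empty centrality table")
    if metric not in table.columns:
        raise ValueError(f"unknown metric: {metric!r}")
    df = table.copy()
    df["_pos"] = range(len(df))
    df = df.sort_values(
        by=[metric, "degree", "_pos"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="_pos")
    if top_k is not None:
        df = df.head(top_k)
    return df
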