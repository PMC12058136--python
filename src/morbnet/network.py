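"""Weighted undirected conditional-dependence network over diseases.

Edge weights are signed aggregated nodewise-regression coefficients; the
``sign_consistent`` flag records whether the two directed coefficients that
produced an edge agreed in sign. Zero-weight pairs are simply absent
(sparsity contract). Serialization: GraphML (lossless attributes) and a
plain TSV edge list; both round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

_EDGE_EPS = 1e-12


def _key(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class PairwiseNetwork:
    nodes: tuple[str, ...]
    edges: dict = field(default_factory=dict)  # (u,v) sorted -> (weight, sign_consistent)

    def __post_init__(self) -> None:
        self.nodes = tuple(self.nodes)
        node_set = set(self.nodes)
        clean = {}
        for (u, v), (w, sc) in dict(self.edges).items():
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node list: {(u, v)}")
            if abs(w) <= _EDGE_EPS:
                continue
            clean[_key(u, v)] = (float(w), bool(sc))
        self.edges = clean

    def add_edge(self, u: str, v: str, weight: float, sign_consistent: bool = True) -> None:
        if u == v:
            raise ValueError(f"self-loop on node {u!r}")
        if abs(weight) <= _EDGE_EPS:
            return
        self.edges[_key(u, v)] = (float(weight), bool(sign_consistent))

    def weight(self, u: str, v: str) -> float:
        return self.edges[_key(u, v)][0]

    def has_edge(self, u: str, v: str) -> bool:
        return _key(u, v) in self.edges

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_set(self) -> set:
        return set(self.edges)

    def degree(self, node: str) -> int:
        return sum(1 for (u, v) in self.edges if node in (u, v))

    def to_networkx(self) -> nx.Graph:
        """Graph with attributes: signed ``weight``, ``abs_weight`` and
        ``dist`` = 1/|weight| (shortest-path length convention for
        association networks: strong association = short distance)."""
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for (u, v), (w, sc) in self.edges.items():
            g.add_edge(u, v, weight=w, abs_weight=abs(w), dist=1.0 / abs(w),
                       sign_consistent=sc)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, nodes: Iterable[str] | None = None) -> "PairwiseNetwork":
        nodes = tuple(nodes) if nodes is not None else tuple(g.nodes)
        edges = {}
        for u, v, data in g.edges(data=True):
            edges[_key(str(u), str(v))] = (
                float(data["weight"]),
                bool(data.get("sign_consistent", True)),
            )
        return cls(nodes=tuple(str(n) for n in nodes), edges=edges)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PairwiseNetwork)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )


def write_network(net: PairwiseNetwork, path, format: str = "graphml") -> None:
    """Write a network as GraphML or a TSV edge list (``source target weight
    sign_consistent``). Weights are serialized with full float precision, so
    a read-back reproduces the network exactly."""
    if format == "graphml":
        g = nx.Graph()
        g.add_nodes_from(net.nodes)
        for (u, v), (w, sc) in net.edges.items():
            g.add_edge(u, v, weight=w, sign_consistent=sc)
        nx.write_graphml(g, path)
    elif format == "edgelist_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("source\ttarget\tweight\tsign_consistent\n")
            for (u, v) in sorted(net.edges):
                w, sc = net.edges[(u, v)]
                fh.write(f"{u}\t{v}\t{w!r}\t{int(sc)}\n")
    else:
        raise ValueError(f"unknown network format: {format!r}")


def read_network(path, format: str = "graphml",
                 nodes: Iterable[str] | None = None) -> PairwiseNetwork:
    if format == "graphml":
        g = nx.read_graphml(path)
        return PairwiseNetwork.from_networkx(g, nodes=nodes)
    if format == "edgelist_tsv":
        edges = {}
        seen = set()
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("source\ttarget"):
                raise ValueError("not a morbnet edge-list TSV")
            for line in fh:
                u, v, w, sc = line.rstrip("\n").split("\t")
                edges[_key(u, v)] = (float(w), bool(int(sc)))
                seen.update((u, v))
        node_list = tuple(nodes) if nodes is not None else tuple(sorted(seen))
        return PairwiseNetwork(nodes=node_list, edges=edges)
    raise ValueError(f"unknown network format: {format!r}")
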