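"""Static network plot convenience (not a figure-replication tool)."""

from __future__ import annotations

import networkx as nx

from .netmetrics import CommunityPartition
from .network import PairwiseNetwork


def plot_network(net: PairwiseNetwork, partition: CommunityPartition | None = None,
                 ax=None, layout_seed: int = 0):
    """Spring-layout plot; node color = community, edge width ~ |weight|."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 8))
    g = net.to_networkx()
    pos = nx.spring_layout(g, seed=layout_seed, weight="abs_weight")
    colors = None
    if partition is not None:
        colors = [partition.assignment[n] for n in g.nodes]
    widths = [2.0 * g[u][v]["abs_weight"] for u, v in g.edges]
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color=colors, cmap="tab10",
                           node_size=300)
    nx.draw_networkx_edges(g, pos, ax=ax, width=widths, alpha=0.6)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=7)
    ax.set_axis_off()
    return ax
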