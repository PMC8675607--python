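"""Node centralities on the thresholded co-expression graph.

Four measures per gene, all in the conventions below:

* DG — degree, the raw neighbour count.
* BW — betweenness, the fraction of shortest paths through the node,
  normalized per connected component by (N-1)(N-2)/2 with N the component
  size; components smaller than 3 give 0.
* CN — closeness, 1 / mean shortest-path length to the other nodes of the
  component; isolated nodes give 0.
* CC — clustering coefficient, 2 e_v / (k_v (k_v - 1)); nodes of degree < 2
  give 0.

Percentile ranks are reported per measure with average-rank tie handling:
percentile 1.0 is the top-ranked gene, so "top 10%" means percentile >= 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .network import CoexpressionNetwork

__all__ = [
    "CentralityTable",
    "MEASURES",
    "degree",
    "betweenness",
    "closeness",
    "clustering_coefficient",
    "percentile_ranks",
    "centrality_table",
]

MEASURES = ("DG", "BW", "CN", "CC")


def degree(graph: nx.Graph) -> dict:
    """Neighbour count per node."""
    return dict(graph.degree())


def betweenness(graph: nx.Graph) -> dict:
    """Shortest-path betweenness, normalized within each connected component.

    For a node v in a component of size N the raw pair sums are divided by
    (N-1)(N-2)/2, so every value lies in [0, 1]; components with fewer than
    3 nodes give 0 by convention.
    """
    out = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) < 3:
            out.update({v: 0.0 for v in comp})
        else:
            out.update(nx.betweenness_centrality(sub, normalized=True))
    return out


def closeness(graph: nx.Graph) -> dict:
    """1 / mean shortest-path distance to the other nodes of the component."""
    out = {}
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        if len(comp) == 1:
            out.update({v: 0.0 for v in comp})
        else:
            # on a connected subgraph the Wasserman-Faust factor is 1, so this
            # is exactly (N-1) / sum of distances = 1 / mean distance
            out.update(nx.closeness_centrality(sub))
    return out


def clustering_coefficient(graph: nx.Graph) -> dict:
    """2 e_v / (k_v (k_v - 1)); 0 for nodes with fewer than 2 neighbours."""
    return {v: float(c) for v, c in nx.clustering(graph).items()}


def percentile_ranks(values: pd.Series) -> pd.Series:
    """Ascending-value percentile with average-rank ties, in (0, 1].

    Equivalent to ranking in descending order and converting to a top-heavy
    percentile: the largest value gets 1.0 and the top decile is >= 0.9.
    """
    if len(values) == 0:
        return values.astype(float)
    return pd.Series(
        rankdata(values.to_numpy(), method="average") / len(values),
        index=values.index,
    )


@dataclass
class CentralityTable:
    """Per-gene DG/BW/CN/CC with percentile ranks for one state network."""

    table: pd.DataFrame  # columns: DG, BW, CN, CC, DG_pct, BW_pct, CN_pct, CC_pct
    state_label: str

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


def centrality_table(net: CoexpressionNetwork) -> CentralityTable:
    """All four centralities plus percentile ranks over the network's nodes."""
    g = net.graph
    nodes = list(g.nodes)
    table = pd.DataFrame(
        {
            "DG": pd.Series(degree(g), dtype=float),
            "BW": pd.Series(betweenness(g), dtype=float),
            "CN": pd.Series(closeness(g), dtype=float),
            "CC": pd.Series(clustering_coefficient(g), dtype=float),
        },
        index=nodes,
    )
    for m in MEASURES:
        table[f"{m}_pct"] = percentile_ranks(table[m])
    table["DG"] = table["DG"].astype(int)
    return CentralityTable(table=table, state_label=net.state_label)
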