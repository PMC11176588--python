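"""Normal-vs-tumor network comparison and betweenness key-gene ranking.

Works on plain unordered edge sets, so the same operations serve the
pathway-level cross-talk networks and the gene-level PathGeNets.  Key genes
are the top-ranked nodes by unnormalised shortest-path betweenness inside a
connected component; only the ranking is interpreted, which makes the result
independent of any normalisation constant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

Edge = tuple[Hashable, Hashable]


def _canon(edges: Iterable[Edge]) -> frozenset[Edge]:
    return frozenset(tuple(sorted(e)) for e in edges)


@dataclass
class NetworkDelta:
    """Edge-set partition of two networks: A-only, B-only and conserved."""

    only_in_a: frozenset[Edge]
    only_in_b: frozenset[Edge]
    conserved: frozenset[Edge]

    def nodes(self, part: str) -> set[Hashable]:
        edges = getattr(self, part)
        return {n for e in edges for n in e}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"node_a": a, "node_b": b, "status": name}
            for name, edges in (
                ("only_in_a", self.only_in_a),
                ("conserved", self.conserved),
                ("only_in_b", self.only_in_b),
            )
            for a, b in sorted(edges)
        ]
        return pd.DataFrame(rows, columns=["node_a", "node_b", "status"])


@dataclass
class KeyGeneRanking:
    """Ordered (gene, betweenness) rows for one component."""

    ranking: pd.DataFrame  # columns: gene, betweenness, rank
    component_id: int
    k: int


def network_difference(net_a: Iterable[Edge], net_b: Iterable[Edge]) -> NetworkDelta:
    """Exact set algebra on unordered edges."""
    a = _canon(net_a)
    b = _canon(net_b)
    return NetworkDelta(a - b, b - a, a & b)


def to_graph(edges: Iterable[Edge], nodes: Iterable[Hashable] = ()) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(_canon(edges))
    return g


def betweenness(net: nx.Graph | Iterable[Edge]) -> dict[Hashable, float]:
    """Unnormalised Brandes betweenness, unordered-pair counting.

    On a path a-b-c the middle node scores 1; the centre of a 4-leaf star
    scores C(4,2) = 6.  Disconnected graphs are handled per component.
    """
    g = net if isinstance(net, nx.Graph) else to_graph(net)
    return nx.betweenness_centrality(g, normalized=False)


def connected_components(net: nx.Graph | Iterable[Edge]) -> list[list[Hashable]]:
    """Components sorted by size (descending), then smallest member."""
    g = net if isinstance(net, nx.Graph) else to_graph(net)
    comps = [sorted(c, key=str) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), str(c[0])))
    return comps


def key_genes(
    net: nx.Graph | Iterable[Edge],
    component: Sequence[Hashable] | None = None,
    k: int = 10,
    component_id: int = 0,
) -> KeyGeneRanking:
    """Top-k genes by betweenness within one component's induced subgraph.

    Ties at the cut are broken lexicographically (and logged); when k
    exceeds the component size the full ranking is returned with a warning.
    """
    g = net if isinstance(net, nx.Graph) else to_graph(net)
    if component is None:
        comps = connected_components(g)
        component = comps[0] if comps else []
    missing = set(component) - set(g.nodes)
    if missing:
        raise ValueError(f"component members absent from network: {sorted(missing, key=str)[:5]}")
    sub = g.subgraph(component)
    scores = nx.betweenness_centrality(sub, normalized=False)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], str(kv[0])))
    if k > len(ordered):
        logger.warning(
            "k=%d exceeds component size %d; returning full ranking", k, len(ordered)
        )
    top = ordered[:k]
    if len(ordered) > len(top) and top and ordered[len(top)][1] == top[-1][1]:
        logger.info(
            "betweenness tie at rank %d broken lexicographically", len(top)
        )
    df = pd.DataFrame(top, columns=["gene", "betweenness"])
    df["rank"] = range(1, len(df) + 1)
    return KeyGeneRanking(df, component_id, k)
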