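"""Network topology statistics and Louvain community detection.

Local metrics follow the unweighted conventions: degree d(i) is the
adjacency row sum; betweenness b(i) sums, over ordered node pairs (t, s)
with t != s != i, the fraction of geodesics between t and s passing
through i (raw, unnormalized); the clustering coefficient divides the
triangles at i by the connected triples d(i)(d(i)-1)/2 and is defined as
0 for nodes of degree 0 or 1. Communities come from seeded Louvain
modularity maximization; the participation ratio of a community is its
OTU count over its metabolite count.
"""

from __future__ import annotations

import dataclasses
import math

import networkx as nx
import numpy as np
import pandas as pd

from .io import OTU, METABOLITE, Network

__all__ = [
    "NodeMetrics",
    "CommunityPartition",
    "degree",
    "betweenness",
    "clustering_coefficient",
    "node_metrics",
    "louvain",
    "modularity",
    "participation_ratio",
]


def _graph(net: Network | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, Network) else net


@dataclasses.dataclass
class NodeMetrics:
    """Per-node degree, betweenness and clustering coefficient."""

    table: pd.DataFrame  # columns: degree, betweenness, clustering

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="node")


@dataclasses.dataclass
class CommunityPartition:
    """Node -> community id mapping with the partition's modularity Q."""

    membership: pd.Series
    q: float

    @property
    def n_communities(self) -> int:
        return self.membership.nunique()

    def communities(self) -> dict[int, set]:
        return {
            int(c): set(idx)
            for c, idx in self.membership.groupby(self.membership).groups.items()
        }


def degree(net: Network | nx.Graph) -> pd.Series:
    g = _graph(net)
    return pd.Series(dict(g.degree()), dtype=int).reindex(list(g.nodes))


def betweenness(net: Network | nx.Graph, normalized: bool = False) -> pd.Series:
    """Geodesic betweenness over *ordered* pairs (t, s), t != s != i.

    Unnormalized by default: the path A-B-C gives b(B) = 2, a star center
    with three leaves gives 6. With ``normalized=True`` values are divided
    by (n-1)(n-2), the count of ordered pairs excluding i.
    """
    g = _graph(net)
    b = nx.betweenness_centrality(g, normalized=False)
    # networkx counts unordered pairs on undirected graphs; double for ordered
    out = pd.Series({n: 2.0 * v for n, v in b.items()}).reindex(list(g.nodes))
    if normalized:
        n = g.number_of_nodes()
        denom = (n - 1) * (n - 2) if n > 2 else 1
        out = out / denom
    return out


def clustering_coefficient(net: Network | nx.Graph) -> pd.Series:
    """Triangles at i over connected triples d(i)(d(i)-1)/2; 0 when d(i) <= 1."""
    g = _graph(net)
    return pd.Series(nx.clustering(g)).reindex(list(g.nodes)).astype(float)


def node_metrics(net: Network | nx.Graph) -> NodeMetrics:
    return NodeMetrics(
        pd.DataFrame(
            {
                "degree": degree(net),
                "betweenness": betweenness(net),
                "clustering": clustering_coefficient(net),
            }
        )
    )


def louvain(
    net: Network | nx.Graph, seed: int = 0, resolution: float = 1.0
) -> CommunityPartition:
    """Seeded Louvain modularity maximization.

    Community ids are re-indexed by decreasing community size (ties by the
    smallest contained node in graph order) so output is stable for a
    given seed.
    """
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("cannot detect communities in an empty network")
    comms = nx.community.louvain_communities(g, seed=seed, resolution=resolution)
    order = {n: i for i, n in enumerate(g.nodes)}
    comms = sorted(comms, key=lambda c: (-len(c), min(order[n] for n in c)))
    membership = pd.Series(
        {n: cid for cid, comm in enumerate(comms) for n in comm}
    ).reindex(list(g.nodes))
    part = CommunityPartition(membership, 0.0)
    part.q = modularity(g, membership)
    return part


def modularity(net: Network | nx.Graph, partition: pd.Series | dict) -> float:
    """Newman modularity Q = sum_c [ e_c/m - (d_c / 2m)^2 ].

    ``partition`` maps every node to a community id; an uncovered node is
    an error. An edgeless graph has Q = 0 by convention.
    """
    g = _graph(net)
    part = dict(partition) if not isinstance(partition, dict) else partition
    missing = [n for n in g.nodes if n not in part or pd.isna(part[n])]
    if missing:
        raise ValueError(f"partition does not cover nodes: {missing}")
    m = g.number_of_edges()
    if m == 0:
        return 0.0
    intra: dict = {}
    deg_sum: dict = {}
    for n, d in g.degree():
        deg_sum[part[n]] = deg_sum.get(part[n], 0) + d
    for u, v in g.edges:
        if part[u] == part[v]:
            intra[part[u]] = intra.get(part[u], 0) + 1
    q = 0.0
    for c, dc in deg_sum.items():
        q += intra.get(c, 0) / m - (dc / (2.0 * m)) ** 2
    return q


def participation_ratio(
    partition: CommunityPartition | pd.Series, kinds: pd.Series | dict
) -> pd.Series:
    """Per-community ratio of OTU node count to metabolite node count.

    Communities without metabolite members get ``inf`` (flagged rather
    than dropped).
    """
    membership = (
        partition.membership
        if isinstance(partition, CommunityPartition)
        else pd.Series(partition)
    )
    kinds = pd.Series(kinds)
    out = {}
    for cid, nodes in membership.groupby(membership).groups.items():
        k = kinds.loc[list(nodes)]
        n_otu = int((k == OTU).sum())
        n_met = int((k == METABOLITE).sum())
        out[int(cid)] = n_otu / n_met if n_met else math.inf
    return pd.Series(out).sort_index()
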