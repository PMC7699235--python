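"""Cross-omics correlation network: all-against-all Pearson, FDR threshold.

Screened features (z-scored across subjects) are cross-correlated against
one another; p-values come from the Student-t transform of r with n-2
degrees of freedom, Benjamini-Hochberg correction runs over the feature-
pair upper triangle, and the significant pairs (q <= alpha, either sign)
become the edges of a binarized adjacency. Nodes left without any edge
are pruned; connected components are reported largest-first.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io import Network
from .preprocess import ZScoreMatrix, bh_fdr

__all__ = ["CorrelationResult", "correlate", "threshold_network", "components"]


@dataclasses.dataclass
class CorrelationResult:
    """Symmetric feature x feature r, p and BH q matrices."""

    r: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame

    @property
    def feature_ids(self) -> list:
        return list(self.r.index)

    @property
    def n_samples_used(self) -> int | None:
        return getattr(self, "_n", None)


def correlation_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r at sample size n via t = r sqrt(n-2)/sqrt(1-r^2)."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # |r| = 1 gives an infinite t statistic -> p = 0
    return np.where(np.isclose(np.abs(r), 1.0), 0.0, p)


def correlate(z: ZScoreMatrix | pd.DataFrame) -> CorrelationResult:
    """Pairwise Pearson correlation of features across subjects.

    Needs at least 4 subjects and 2 features. q-values are BH-adjusted
    over the upper triangle only (each pair tested once) and mirrored.
    """
    data = z.values if isinstance(z, ZScoreMatrix) else pd.DataFrame(z)
    n = data.shape[1]
    if n < 4:
        raise ValueError("correlation p-values need at least 4 subjects")
    if data.shape[0] < 2:
        raise ValueError("need at least 2 features to correlate")
    x = data.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if np.any(sd == 0):
        raise ValueError("constant features must be excluded before correlating")
    r = np.corrcoef(x)
    r = np.clip(r, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    p = correlation_pvalue(r, n)
    np.fill_diagonal(p, 0.0)
    iu = np.triu_indices_from(r, k=1)
    q = np.zeros_like(p)
    if iu[0].size:
        q_flat = bh_fdr(p[iu])
        q[iu] = q_flat
        q = q + q.T
    ids = data.index
    res = CorrelationResult(
        pd.DataFrame(r, index=ids, columns=ids),
        pd.DataFrame(p, index=ids, columns=ids),
        pd.DataFrame(q, index=ids, columns=ids),
    )
    res._n = n
    return res


def threshold_network(
    c: CorrelationResult,
    kinds: pd.Series | dict | None = None,
    alpha: float = 0.05,
) -> Network:
    """Binarize the correlation matrix at q <= alpha into a network.

    Edges keep the correlation value and its sign as attributes; nodes
    that end up with no significant edge are removed, so an all-null
    correlation structure yields an empty network. Node labels are
    1-based in feature order over the retained nodes.
    """
    ids = c.feature_ids
    qv = c.q.to_numpy()
    rv = c.r.to_numpy()
    g = nx.Graph()
    iu, ju = np.triu_indices(len(ids), k=1)
    sig = qv[iu, ju] <= alpha
    for i, j in zip(iu[sig], ju[sig]):
        r = float(rv[i, j])
        g.add_edge(ids[i], ids[j], r=r, sign=1 if r >= 0 else -1)
    # node insertion in feature order for stable 1-based labels
    ordered = nx.Graph()
    for node in ids:
        if node in g:
            ordered.add_node(node)
    ordered.add_edges_from(g.edges(data=True))
    return Network.from_graph(ordered, kinds=kinds)


def components(net: Network) -> list[set]:
    """Connected components as node sets, sorted by size descending."""
    comps = [set(c) for c in nx.connected_components(net.graph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(map(str, c))))
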