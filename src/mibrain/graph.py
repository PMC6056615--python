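"""Binary brain networks and their topology metrics.

A subject's MI connectivity matrix is reduced to an undirected, unweighted
graph by proportional thresholding: the strongest fraction ``p`` of the
n(n-1)/2 unique edges is retained (round-half-up, so p = 0.20 on 16 channels
keeps exactly 24 of 120 edges), which equalises edge counts across subjects
before any group comparison. Metrics:

* per-node clustering coefficient  C_i = 2 e_i / (k_i (k_i - 1)), zero for
  nodes of degree <= 1, with the network summarised by the mean over nodes;
* betweenness centrality, the sum over unordered node pairs {j, k} (j, k != i)
  of the fraction of shortest j-k paths passing through i, unnormalised;
* the count of edges whose endpoints lie in opposite hemispheres under the
  10-20 montage's odd/even split.

Graph algorithms delegate to networkx; the conventions above pin down the
exact variants used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import networkx as nx
import numpy as np

from .mi import MIMatrix
from .recording import LEFT_CHANNELS, RIGHT_CHANNELS


@dataclass(frozen=True)
class HemisphereMap:
    """Left/right electrode partition; defaults to the 16-channel 10-20 split
    (odd-numbered electrodes left, even right)."""

    left: frozenset = LEFT_CHANNELS
    right: frozenset = RIGHT_CHANNELS

    def __post_init__(self):
        if self.left & self.right:
            raise ValueError("hemisphere sets must be disjoint")

    def side(self, label: str) -> str:
        if label in self.left:
            return "left"
        if label in self.right:
            return "right"
        raise KeyError(
            f"channel {label!r} is not assigned to a hemisphere; "
            f"known labels: {sorted(self.left | self.right)}"
        )


@dataclass
class BinaryNetwork:
    """Undirected, unweighted network from proportional thresholding."""

    adjacency: np.ndarray
    threshold_fraction: float
    retained_edges: int
    channel_labels: tuple

    def __post_init__(self):
        self.adjacency = np.asarray(self.adjacency, dtype=bool)
        self.channel_labels = tuple(self.channel_labels)
        n = len(self.channel_labels)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square and match labels")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(self.adjacency)):
            raise ValueError("adjacency diagonal must be zero")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edge_list(self) -> List[Tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return list(zip(i.tolist(), j.tolist()))

    def to_networkx(self) -> nx.Graph:
        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        G.add_edges_from(self.edge_list())
        return G


@dataclass
class NodeMetrics:
    """Per-node topology metrics of one binary network."""

    clustering: np.ndarray
    betweenness: np.ndarray
    channel_labels: tuple

    @property
    def mean_clustering(self) -> float:
        return float(np.mean(self.clustering))


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def rank_order_edges(mi: MIMatrix) -> List[Tuple[Tuple[str, str], float]]:
    """Unique off-diagonal edges sorted by descending MI.

    Ties are broken by the lexicographic (label_i, label_j) order of the edge
    endpoints, so the ranking is deterministic across platforms. Length is
    n(n-1)/2 — 120 entries for 16 channels.
    """
    if not np.allclose(mi.values, mi.values.T):
        raise ValueError("MI matrix must be symmetric")
    entries = []
    for (i, j), value in mi.upper_triangle_pairs():
        entries.append(((mi.channel_labels[i], mi.channel_labels[j]), float(value)))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return entries


def proportional_threshold(mi: MIMatrix, fraction: float) -> BinaryNetwork:
    """Retain the strongest ``round(fraction * n_pairs)`` edges (half-up).

    Edge selection is by descending MI with deterministic lexicographic
    tie-breaking, so networks at nested fractions are nested whenever the MI
    values at the cut are distinct.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"threshold fraction must be in (0, 1], got {fraction}")
    n = mi.n_channels
    n_pairs = n * (n - 1) // 2
    k = _round_half_up(fraction * n_pairs)
    ranked = rank_order_edges(mi)
    label_index = {label: idx for idx, label in enumerate(mi.channel_labels)}
    adjacency = np.zeros((n, n), dtype=bool)
    for (la, lb), _ in ranked[:k]:
        i, j = label_index[la], label_index[lb]
        adjacency[i, j] = adjacency[j, i] = True
    return BinaryNetwork(
        adjacency=adjacency,
        threshold_fraction=fraction,
        retained_edges=k,
        channel_labels=mi.channel_labels,
    )


def clustering_coefficient(net: BinaryNetwork) -> NodeMetrics:
    """Per-node clustering C_i = 2 e_i / (k_i (k_i - 1)).

    ``e_i`` counts edges among the neighbours of i; nodes with at most one
    neighbour get C_i = 0. Betweenness in the returned metrics is filled too
    (see :func:`betweenness_centrality`).
    """
    return node_metrics(net)


def betweenness_centrality(net: BinaryNetwork) -> NodeMetrics:
    """Unnormalised betweenness over unordered node pairs.

    For disconnected pairs (no path) the contribution is zero. On a path
    A-B-C the centre scores 1; on a star the hub scores C(n_leaves, 2).
    """
    return node_metrics(net)


def node_metrics(net: BinaryNetwork, normalized_betweenness: bool = False) -> NodeMetrics:
    """Clustering coefficient and betweenness centrality for every node."""
    G = net.to_networkx()
    clustering = nx.clustering(G)
    betweenness = nx.betweenness_centrality(G, normalized=normalized_betweenness)
    n = net.n_nodes
    return NodeMetrics(
        clustering=np.array([clustering[i] for i in range(n)], dtype=float),
        betweenness=np.array([betweenness[i] for i in range(n)], dtype=float),
        channel_labels=net.channel_labels,
    )


def interhemispheric_edge_count(net: BinaryNetwork, hemisphere_map: HemisphereMap = HemisphereMap()) -> int:
    """Number of retained edges with one endpoint in each hemisphere."""
    sides = [hemisphere_map.side(label) for label in net.channel_labels]
    count = 0
    for i, j in net.edge_list():
        if sides[i] != sides[j]:
            count += 1
    return count


DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.10, 0.301, 0.01), 2))


def threshold_sweep(
    mi: MIMatrix,
    fractions: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    hemisphere_map: HemisphereMap = HemisphereMap(),
) -> List[Dict]:
    """Threshold the MI matrix at each fraction and compute all metrics.

    The default grid is 0.10 to 0.30 in 0.01 steps (21 thresholds). Returns
    one record per fraction with the binary network, node metrics, and the
    interhemispheric edge count.
    """
    fractions = list(fractions)
    if any(f2 < f1 for f1, f2 in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be sorted ascending")
    records = []
    for fraction in fractions:
        net = proportional_threshold(mi, fraction)
        metrics = node_metrics(net)
        records.append(
            {
                "fraction": float(fraction),
                "network": net,
                "metrics": metrics,
                "interhemispheric_edges": interhemispheric_edge_count(net, hemisphere_map),
                "mean_clustering": metrics.mean_clustering,
            }
        )
    return records
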