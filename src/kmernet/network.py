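"""Bipartite promoter-enhancer interaction graph and the edge-degree grid.

The node degree of a promoter is the number of distinct enhancers it
interacts with, and vice versa; the graph carries no edge weights (the
unweighted degree, not the contact frequency, is the measure of
interest).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_DEGREE_CAP = 10
DEFAULT_GRID_RANGE = (1, 5)


@dataclass
class InteractionNetwork:
    """Bipartite promoter-enhancer graph with precomputed degrees."""

    promoters: set
    enhancers: set
    edges: list
    degree: dict

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def graph(self) -> nx.Graph:
        """The network as a networkx bipartite graph."""
        g = nx.Graph()
        g.add_nodes_from(self.promoters, bipartite="promoter")
        g.add_nodes_from(self.enhancers, bipartite="enhancer")
        g.add_edges_from(self.edges)
        return g

    def node_type(self, node_id) -> str:
        if node_id in self.promoters:
            return "promoter"
        if node_id in self.enhancers:
            return "enhancer"
        raise KeyError(node_id)


def build_network(records) -> InteractionNetwork:
    """Build the bipartite network from interaction records.

    ``records`` may be :class:`~kmernet.io_formats.InteractionRecord`
    objects or plain ``(promoter_id, enhancer_id)`` pairs, already
    deduplicated.  A node id appearing on both sides violates the
    bipartite assumption and is an error.
    """
    pairs = []
    for rec in records:
        if isinstance(rec, tuple):
            pairs.append(rec)
        else:
            pairs.append((rec.promoter_id, rec.enhancer_id))
    promoters = {p for p, _ in pairs}
    enhancers = {e for _, e in pairs}
    overlap = promoters & enhancers
    if overlap:
        raise ValueError(
            f"node ids appear as both promoter and enhancer: {sorted(overlap)[:5]}"
        )
    degree = Counter()
    for p, e in pairs:
        degree[p] += 1
        degree[e] += 1
    network = InteractionNetwork(
        promoters=promoters, enhancers=enhancers, edges=pairs, degree=dict(degree)
    )
    _log_summary(network)
    return network


def _log_summary(network: InteractionNetwork) -> None:
    p_hist = Counter(network.degree[p] for p in network.promoters)
    e_hist = Counter(network.degree[e] for e in network.enhancers)
    logger.info(
        "network: %d promoters, %d enhancers, %d edges; "
        "promoter degree histogram %s; enhancer degree histogram %s",
        len(network.promoters), len(network.enhancers), network.n_edges,
        dict(sorted(p_hist.items())), dict(sorted(e_hist.items())),
    )


def subset_network(network: InteractionNetwork, keep_ids) -> InteractionNetwork:
    """Restrict the network to nodes in ``keep_ids``.

    Edges with a removed endpoint disappear; degrees are recomputed, so
    a surviving node's degree can drop.  Nodes isolated by the removal
    are kept in the node sets with degree 0 (downstream statistics skip
    them, with a log line).
    """
    keep = set(keep_ids)
    promoters = network.promoters & keep
    enhancers = network.enhancers & keep
    edges = [(p, e) for p, e in network.edges if p in keep and e in keep]
    degree = Counter()
    for p, e in edges:
        degree[p] += 1
        degree[e] += 1
    for node in promoters | enhancers:
        degree.setdefault(node, 0)
    removed_edges = network.n_edges - len(edges)
    if removed_edges:
        logger.info("subset: removed %d edges with dropped endpoints", removed_edges)
    return InteractionNetwork(promoters, enhancers, edges, dict(degree))


@dataclass
class EdgeDegreeGrid:
    """Edges binned simultaneously by promoter degree and enhancer degree.

    ``counts[i, j]`` is the number of edges whose promoter has degree
    ``degrees[i]`` and whose enhancer has degree ``degrees[j]``;
    ``frequency`` divides by the total edge count of the whole network
    (not just the grid range); ``mean_distance`` is NaN for empty cells.
    """

    degrees: np.ndarray
    counts: np.ndarray
    frequency: np.ndarray
    mean_distance: np.ndarray | None
    total_edges: int

    def to_frame(self, layer: str = "frequency") -> pd.DataFrame:
        data = {"frequency": self.frequency, "counts": self.counts,
                "mean_distance": self.mean_distance}[layer]
        if data is None:
            raise ValueError("grid has no distance layer")
        return pd.DataFrame(
            data,
            index=pd.Index(self.degrees, name="promoter_degree"),
            columns=pd.Index(self.degrees, name="enhancer_degree"),
        )


def edge_degree_grid(
    network: InteractionNetwork,
    edge_distances: dict | None = None,
    degree_range: tuple[int, int] = DEFAULT_GRID_RANGE,
) -> EdgeDegreeGrid:
    """Bin edges by (promoter degree, enhancer degree).

    ``edge_distances`` maps ``(promoter_id, enhancer_id)`` to a k-mer
    distance; omit it for a frequency-only grid.
    """
    lo, hi = degree_range
    if hi < lo:
        raise ValueError(f"inverted degree_range {degree_range}")
    degrees = np.arange(lo, hi + 1)
    n = degrees.size
    counts = np.zeros((n, n), dtype=np.int64)
    dist_sum = np.zeros((n, n))
    for edge in network.edges:
        p, e = edge
        dp, de = network.degree[p], network.degree[e]
        if not (lo <= dp <= hi and lo <= de <= hi):
            continue
        i, j = dp - lo, de - lo
        counts[i, j] += 1
        if edge_distances is not None:
            dist_sum[i, j] += edge_distances[edge]
    total = network.n_edges
    frequency = counts / total if total else counts.astype(float)
    if edge_distances is not None:
        with np.errstate(invalid="ignore"):
            mean_distance = np.where(counts > 0, dist_sum / np.maximum(counts, 1), np.nan)
    else:
        mean_distance = None
    return EdgeDegreeGrid(degrees, counts, frequency, mean_distance, total)
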