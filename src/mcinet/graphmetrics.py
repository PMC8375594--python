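"""Nodal metrics on binary brain networks.

Three per-node measures are extracted from every binarized network:

* nodal degree ``K_i = sum_j b_ij``;
* nodal path length ``L_i = sum_{j != i} L_ij / (V - 1)`` with ``L_ij`` the
  BFS shortest-path distance (unreachable pairs contribute ``V``, a finite
  penalty that keeps the measure defined on the disconnected graphs sparse
  costs produce; alternatively average over reachable pairs only);
* betweenness centrality ``B_i``: over unordered pairs {j, m} avoiding i,
  the fraction of their shortest paths passing through i.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path

from .networks import BinaryNetwork


@dataclass
class NodalMetrics:
    nl: np.ndarray  # nodal path length
    nd: np.ndarray  # nodal degree
    bc: np.ndarray  # betweenness centrality


def _adjacency(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    adj = net.adjacency if isinstance(net, BinaryNetwork) else np.asarray(net)
    return adj.astype(np.int8, copy=False)


def nodal_degree(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    return _adjacency(net).sum(axis=1).astype(float)


def nodal_path_length(
    net: BinaryNetwork | np.ndarray, unreachable: str = "penalty"
) -> np.ndarray:
    """Mean BFS distance from each node to all others.

    ``unreachable="penalty"`` substitutes V for unreachable pairs;
    ``"reachable"`` averages over reachable pairs only (isolated nodes get V).
    """
    adj = _adjacency(net)
    v = adj.shape[0]
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    off = ~np.eye(v, dtype=bool)
    if unreachable == "penalty":
        dist = np.where(np.isinf(dist), float(v), dist)
        return dist[off].reshape(v, v - 1).mean(axis=1)
    if unreachable == "reachable":
        finite = np.isfinite(dist) & off
        counts = finite.sum(axis=1)
        sums = np.where(finite, dist, 0.0).sum(axis=1)
        return np.where(counts > 0, sums / np.maximum(counts, 1), float(v))
    raise ValueError(f"unknown unreachable convention {unreachable!r}")


def betweenness(net: BinaryNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized betweenness over unordered node pairs (Brandes)."""
    adj = _adjacency(net)
    graph = nx.from_numpy_array(adj)
    bc = nx.betweenness_centrality(graph, normalized=False)
    return np.array([bc[i] for i in range(adj.shape[0])])


def nodal_metrics(net: BinaryNetwork | np.ndarray, unreachable: str = "penalty") -> NodalMetrics:
    return NodalMetrics(
        nl=nodal_path_length(net, unreachable=unreachable),
        nd=nodal_degree(net),
        bc=betweenness(net),
    )
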