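"""Weighted brain-network construction and cost-based binarization.

Two weighted networks feed the pipeline:

* a *structural* (thickness-similarity) network, ``w(i, j) =
  exp(-(ct_i - ct_j)^2 / alpha)`` over the 68 Desikan-Killiany regions; and
* a *functional* network of Fisher z-transformed Pearson correlations
  between AAL region time series.

Both are thresholded to binary graphs at a connection *cost*: the fraction
of the V(V-1)/2 possible edges that is retained, keeping the largest
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_R_CLIP = 1.0 - 1e-7  # keeps atanh finite for perfectly correlated rows


@dataclass
class BrainNetwork:
    """Symmetric weighted connectivity matrix with provenance."""

    kind: str  # "structural" | "functional"
    band: str  # "full" | "slow4" | "slow5" | "none"
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weights must be square, got {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights contain non-finite entries")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0.0):
            raise ValueError("diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class BinaryNetwork:
    """0/1 adjacency obtained by thresholding a weighted network at a cost."""

    adjacency: np.ndarray
    cost: float
    edge_count: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def thickness_network(ct: np.ndarray, alpha: float = 0.01) -> BrainNetwork:
    """Gaussian-kernel similarity network on cortical thickness.

    ``alpha`` is the kernel width; the default 0.01 mm^2 makes the weight
    drop to exp(-1) for a thickness difference of 0.1 mm.
    """
    ct = np.asarray(ct, dtype=float)
    if ct.ndim != 1:
        raise ValueError("ct must be a 1-D vector")
    if not np.all(np.isfinite(ct)):
        raise ValueError("ct contains non-finite values")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    diff = ct[:, None] - ct[None, :]
    weights = np.exp(-(diff**2) / alpha)
    np.fill_diagonal(weights, 0.0)
    return BrainNetwork(kind="structural", band="none", weights=weights)


def functional_network(ts: np.ndarray, band: str = "none") -> BrainNetwork:
    """Fisher z-transformed Pearson-correlation network of ROI time series."""
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("ts must be a regions x time matrix")
    if ts.shape[1] < 3:
        raise ValueError("need at least 3 time points")
    sd = ts.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(f"region {flat[0]} has a constant time series")
    r = np.corrcoef(ts)
    z = np.arctanh(np.clip(r, -_R_CLIP, _R_CLIP))
    z = (z + z.T) / 2.0
    np.fill_diagonal(z, 0.0)
    return BrainNetwork(kind="functional", band=band, weights=z)


def binarize_at_cost(
    net: BrainNetwork, cost: float, rank_mode: str = "signed"
) -> BinaryNetwork:
    """Keep the ``round(cost * V(V-1)/2)`` largest-weight edges.

    ``rank_mode="signed"`` ranks edges by signed weight (a strong negative
    correlation is a weak edge); ``"absolute"`` ranks by magnitude.  Ties at
    the cutoff break deterministically by ascending (i, j) order, so lower
    costs always produce edge subsets of higher costs.
    """
    if not 0.0 < cost < 1.0:
        raise ValueError(f"cost must be in (0, 1), got {cost}")
    if rank_mode not in ("signed", "absolute"):
        raise ValueError(f"unknown rank_mode {rank_mode!r}")
    v = net.n_nodes
    n_possible = v * (v - 1) // 2
    k = int(round(cost * n_possible))
    iu, ju = np.triu_indices(v, k=1)
    w = net.weights[iu, ju]
    if rank_mode == "absolute":
        w = np.abs(w)
    # stable sort on ascending (i, j) then stable descending-weight sort
    order = np.argsort(-w, kind="stable")
    keep = order[:k]
    adjacency = np.zeros((v, v), dtype=np.int8)
    adjacency[iu[keep], ju[keep]] = 1
    adjacency |= adjacency.T
    return BinaryNetwork(adjacency=adjacency, cost=cost, edge_count=k)
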