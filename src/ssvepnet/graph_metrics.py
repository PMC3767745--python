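"""Weighted graph topology: clustering, path length, efficiencies.

All metrics operate on symmetric nonnegative weight matrices with zero
diagonal (coherence networks).  Conventions:

* Clustering uses the Onnela cube-root-product form with weights normalized
  by the network maximum: C_i = Σ_{j,h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3} / (k_i(k_i−1)),
  C_i = 0 for degree < 2; the network value averages over all N nodes.
* Edge length is the inverse weight 1/w_ij (strong coupling = short edge);
  absent edges have infinite length.
* The characteristic path length is the harmonic mean of the all-pairs
  shortest path lengths, L = N(N−1) / Σ_{i≠j} 1/L_ij, which stays finite
  when some pairs are disconnected; the global efficiency is its exact
  inverse, E_glob = mean of 1/L_ij.
* Local efficiency of node i is the global efficiency of the subgraph
  induced by i's direct neighbours (i itself excluded, original weights,
  paths confined to the subgraph); 0 for degree < 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import CoherenceNetwork

__all__ = [
    "TopologyMetrics",
    "node_degrees",
    "clustering_coefficient",
    "shortest_path_lengths",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "mean_connectivity",
    "network_metrics",
]


class DisconnectedNetworkError(ValueError):
    """Raised when every node pair is disconnected (path length undefined)."""


@dataclass
class TopologyMetrics:
    """The four weighted topology metrics of one network."""

    clustering: float
    clustering_per_node: np.ndarray
    path_length: float
    global_eff: float
    local_eff: float
    local_eff_per_node: np.ndarray


def _weights(network: CoherenceNetwork | np.ndarray) -> np.ndarray:
    if isinstance(network, CoherenceNetwork):
        return network.weights
    w = np.asarray(network, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {w.shape}")
    return w


def node_degrees(network: CoherenceNetwork | np.ndarray) -> np.ndarray:
    """k_i: number of neighbours joined by a nonzero weight."""
    w = _weights(network)
    return (w > 0).sum(axis=1).astype(int)


def clustering_coefficient(
    network: CoherenceNetwork | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node and its mean over all N nodes."""
    w = _weights(network)
    k = node_degrees(w)
    w_max = w.max()
    if w_max == 0:
        return np.zeros(w.shape[0]), 0.0
    w_hat = np.cbrt(w / w_max)
    # Diagonal of the cubed matrix counts each (j, h) ordered pair once.
    tri = np.einsum("ij,jh,hi->i", w_hat, w_hat, w_hat)
    per_node = np.zeros(w.shape[0])
    ok = k >= 2
    per_node[ok] = tri[ok] / (k[ok] * (k[ok] - 1))
    return per_node, float(per_node.mean())


def shortest_path_lengths(network: CoherenceNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths over edge lengths 1/w_ij.

    Disconnected pairs get ``inf``; the diagonal is 0.
    """
    w = _weights(network)
    n = w.shape[0]
    i, j = np.nonzero(w)
    lengths = csr_matrix((1.0 / w[i, j], (i, j)), shape=(n, n))
    return dijkstra(lengths, directed=False)


def characteristic_path_length(network: CoherenceNetwork | np.ndarray) -> float:
    """Harmonic-mean path length L = N(N−1) / Σ_{i≠j} 1/L_ij (1/∞ = 0)."""
    dist = shortest_path_lengths(network)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("path length needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(dist[off]), 0.0, 1.0 / dist[off])
    total = inv.sum()
    if total == 0:
        raise DisconnectedNetworkError(
            "all node pairs are disconnected; characteristic path length undefined"
        )
    return float(n * (n - 1) / total)


def global_efficiency(network: CoherenceNetwork | np.ndarray) -> float:
    """E_glob = mean over ordered pairs of 1/L_ij; disconnected pairs add 0."""
    w = _weights(network)
    n = w.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    dist = shortest_path_lengths(w)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(dist[off]), 0.0, 1.0 / dist[off])
    return float(inv.sum() / (n * (n - 1)))


def local_efficiency(
    network: CoherenceNetwork | np.ndarray,
) -> tuple[np.ndarray, float]:
    """E_loc(i): global efficiency of i's neighbour subgraph; mean over N."""
    w = _weights(network)
    n = w.shape[0]
    per_node = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(w[i] > 0)
        if nb.size < 2:
            continue
        per_node[i] = global_efficiency(w[np.ix_(nb, nb)])
    return per_node, float(per_node.mean())


def mean_connectivity(network: CoherenceNetwork | np.ndarray) -> float:
    """Mean weight of the network's present (nonzero) edges; 0 if edgeless."""
    w = _weights(network)
    iu = np.triu_indices(w.shape[0], k=1)
    vals = w[iu]
    vals = vals[vals > 0]
    return float(vals.mean()) if vals.size else 0.0


def network_metrics(network: CoherenceNetwork | np.ndarray) -> TopologyMetrics:
    """All four topology metrics of one network."""
    c_node, c_mean = clustering_coefficient(network)
    e_node, e_mean = local_efficiency(network)
    return TopologyMetrics(
        clustering=c_mean,
        clustering_per_node=c_node,
        path_length=characteristic_path_length(network),
        global_eff=global_efficiency(network),
        local_eff=e_mean,
        local_eff_per_node=e_node,
    )
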