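"""Sparsity search and top-edge thresholding ("Network 0").

Coherence is never exactly zero, so an unthresholded network is complete and
full of spurious weak edges.  The group-level sparsity value is found by
scanning a weight cutoff t from 0 to 1 in fixed steps and deleting, in every
subject's original network, the edges with weight < t.  The first cutoff at
which any network acquires an isolated ("sole") node stops the scan; the
sparsity is the edge fraction remaining at the preceding cutoff — the
smallest common edge fraction that keeps every network free of isolated
nodes.  Each network is then reduced to its top-weight edges so that all
subjects share the same node and edge counts (Network 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .connectivity import CoherenceNetwork

__all__ = ["SparsityResult", "find_sparsity", "apply_sparsity", "round_half_up"]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves upward."""
    return int(math.floor(x + 0.5))


@dataclass
class SparsityResult:
    """Outcome of the group sparsity scan."""

    sparsity: float
    #: First scanned cutoff at which some network had an isolated node
    #: (NaN when no cutoff up to 1 isolates any node).
    critical_threshold: float
    #: Common number of edges each thresholded network keeps.
    n_edges_kept: int


def _upper_weights(net: CoherenceNetwork) -> np.ndarray:
    iu = np.triu_indices(net.n_nodes, k=1)
    return net.weights[iu]


def _has_isolated_node(weights: np.ndarray, cutoff: float) -> bool:
    kept = np.where(weights >= cutoff, weights, 0.0)
    np.fill_diagonal(kept, 0.0)
    return bool(np.any((kept > 0).sum(axis=1) == 0))


def find_sparsity(
    networks: list[CoherenceNetwork],
    step: float = 0.01,
) -> SparsityResult:
    """Scan cutoffs t = 0, step, 2·step, … 1 over all networks jointly.

    Deleting edges with weight < t in every network, the first t* at which
    any network contains a node with no remaining edges stops the scan.  The
    sparsity is the maximum over networks of the edge fraction remaining at
    t* − step: the smallest common fraction guaranteeing every network stays
    free of isolated nodes.
    """
    if not networks:
        raise ValueError("need at least one network")
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    n = networks[0].n_nodes
    for net in networks:
        if net.n_nodes != n:
            raise ValueError("networks differ in node count")
    m_max = n * (n - 1) // 2
    weight_mats = [net.weights for net in networks]
    if any(_has_isolated_node(w, np.nextafter(0.0, 1.0)) for w in weight_mats):
        raise ValueError(
            "a network already contains an isolated node at threshold 0 "
            "(input disconnected)"
        )

    n_steps = int(math.ceil(1.0 / step))
    cutoffs = [min(k * step, 1.0) for k in range(n_steps + 1)]
    t_star = None
    for t in cutoffs[1:]:  # t=0 deletes nothing and was checked above
        if any(_has_isolated_node(w, t) for w in weight_mats):
            t_star = t
            break

    if t_star is None:
        final = cutoffs[-1]
        frac = max(
            float(np.sum(_upper_weights(net) >= final)) / m_max
            for net in networks
        )
        return SparsityResult(
            sparsity=frac,
            critical_threshold=float("nan"),
            n_edges_kept=round_half_up(frac * m_max),
        )

    prev = max(t_star - step, 0.0)
    frac = max(
        float(np.sum(_upper_weights(net) >= prev)) / m_max for net in networks
    )
    return SparsityResult(
        sparsity=frac,
        critical_threshold=float(t_star),
        n_edges_kept=round_half_up(frac * m_max),
    )


def apply_sparsity(
    network: CoherenceNetwork,
    sparsity: float,
) -> CoherenceNetwork:
    """Keep the ``round(sparsity · N(N−1)/2)`` largest-weight edges.

    All other weights are set to 0; the node set is unchanged.  Ties at the
    cut are broken deterministically by (weight descending, then
    lexicographic node pair).  The result is the subject's "Network 0".
    """
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {sparsity}")
    n = network.n_nodes
    m_max = n * (n - 1) // 2
    k = round_half_up(sparsity * m_max)
    iu, ju = np.triu_indices(n, k=1)
    w = network.weights[iu, ju]
    nonzero = np.flatnonzero(w > 0)
    if k > nonzero.size:
        raise ValueError(
            f"requested {k} edges but only {nonzero.size} nonzero edges exist"
        )
    labels = network.node_labels
    order = sorted(
        nonzero,
        key=lambda e: (-w[e], labels[iu[e]], labels[ju[e]]),
    )
    keep = order[:k]
    out = np.zeros_like(network.weights)
    out[iu[keep], ju[keep]] = w[keep]
    out = out + out.T
    return CoherenceNetwork(
        node_labels=network.node_labels,
        weights=out,
        stim_freq=network.stim_freq,
        n_epochs_averaged=network.n_epochs_averaged,
    )
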