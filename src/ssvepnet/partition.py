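"""Edge-wise correlation with SNR and the Network 1/2/3 partition.

For every channel pair present in any subject's Network 0, the connection
strengths across subjects are correlated (Pearson) with the subjects' mean
stimulus-band SNRs.  Edges with a significantly positive correlation form
Network 1, significantly negative ones Network 3, and the remainder
Network 2 (alpha = 0.05, uncorrected, matching the group-level screening
this partition performs).  Classification is group-level: the classes are
identical across subjects, only the weights differ.

Because the top-edge thresholding of Network 0 is per subject, subjects'
edge sets differ; the correlation is computed over the union of the edge
sets, a subject lacking an edge contributing weight 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .connectivity import CoherenceNetwork
from .stats import pearson_vectorized

__all__ = [
    "EdgeCorrelation",
    "NetworkPartition",
    "edgewise_correlation",
    "classify_edges",
    "subnetwork",
    "CLASSES",
]

logger = logging.getLogger(__name__)

CLASSES = ("positive", "nonsig", "negative")


@dataclass
class EdgeCorrelation:
    """Per-edge Pearson correlation of weight with SNR across subjects."""

    edges: list[tuple[str, str]]
    r: np.ndarray
    p: np.ndarray
    n: int
    #: Edges whose correlation was undefined (zero weight or SNR variance).
    degenerate: set[tuple[str, str]] = field(default_factory=set)


@dataclass
class NetworkPartition:
    """Group-level class of every edge in the Network-0 union."""

    edge_class: dict[tuple[str, str], str]
    alpha: float

    def edges_of(self, cls: str) -> list[tuple[str, str]]:
        if cls not in CLASSES:
            raise ValueError(f"unknown class {cls!r}; expected one of {CLASSES}")
        return [e for e, c in self.edge_class.items() if c == cls]


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def edge_union(networks: list[CoherenceNetwork]) -> list[tuple[str, str]]:
    """Union of nonzero edge sets across networks, lexicographically sorted."""
    labels = networks[0].node_labels
    present: set[tuple[str, str]] = set()
    for net in networks:
        if net.node_labels != labels:
            raise ValueError("networks have mismatched node labels")
        iu, ju = np.nonzero(np.triu(net.weights, k=1))
        present.update(_edge_key(labels[i], labels[j]) for i, j in zip(iu, ju))
    return sorted(present)


def edge_weight_matrix(
    networks: list[CoherenceNetwork],
    edges: list[tuple[str, str]],
) -> np.ndarray:
    """Subjects × edges weight matrix, zero-filled for absent edges."""
    labels = networks[0].node_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    rows = np.array([idx[a] for a, _ in edges], dtype=int)
    cols = np.array([idx[b] for _, b in edges], dtype=int)
    return np.stack([net.weights[rows, cols] for net in networks])


def edgewise_correlation(
    networks0: list[CoherenceNetwork],
    snrs: list[float] | np.ndarray,
) -> EdgeCorrelation:
    """Pearson r and two-sided p per edge of the Network-0 union.

    Requires at least 3 subjects.  Edges with zero weight variance (or a
    zero-variance SNR vector) get an undefined correlation; they are flagged
    and will fall into the non-significant class.
    """
    snrs = np.asarray(snrs, dtype=float)
    if len(networks0) != snrs.size:
        raise ValueError(
            f"{len(networks0)} networks but {snrs.size} SNR values"
        )
    if snrs.size < 3:
        raise ValueError("need at least 3 subjects for edge-wise correlation")
    edges = edge_union(networks0)
    W = edge_weight_matrix(networks0, edges)  # (S, E)
    r, p = pearson_vectorized(W, snrs)
    degenerate = {edges[e] for e in np.flatnonzero(np.isnan(r))}
    if degenerate:
        logger.warning(
            "undefined correlation (zero variance) for %d edge(s): %s",
            len(degenerate),
            sorted(degenerate),
        )
    return EdgeCorrelation(edges=edges, r=r, p=p, n=snrs.size, degenerate=degenerate)


def classify_edges(corr: EdgeCorrelation, alpha: float = 0.05) -> NetworkPartition:
    """Split edges into positive / negative / non-significant classes.

    positive: p < alpha and r > 0 (Network 1); negative: p < alpha and
    r < 0 (Network 3); everything else, including degenerate edges,
    non-significant (Network 2).  No multiple-testing correction is applied.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    edge_class: dict[tuple[str, str], str] = {}
    for e, r, p in zip(corr.edges, corr.r, corr.p):
        if np.isnan(r) or p >= alpha:
            edge_class[e] = "nonsig"
        elif r > 0:
            edge_class[e] = "positive"
        elif r < 0:
            edge_class[e] = "negative"
        else:  # r == 0 can't be significant, but keep the case explicit
            edge_class[e] = "nonsig"
    return NetworkPartition(edge_class=edge_class, alpha=alpha)


def subnetwork(
    network0: CoherenceNetwork,
    partition: NetworkPartition,
    cls: str,
) -> CoherenceNetwork:
    """This subject's sub-network of one edge class.

    Keeps the same nodes and only the edges of the requested class, with the
    weights they have in this subject's Network 0 (0 where the subject lacks
    the edge).  Isolated nodes are permitted.  The three class sub-networks
    partition Network 0's edges, so their weight matrices sum to Network 0's.
    """
    labels = network0.node_labels
    idx = {lab: i for i, lab in enumerate(labels)}
    out = np.zeros_like(network0.weights)
    for a, b in partition.edges_of(cls):
        i, j = idx[a], idx[b]
        out[i, j] = out[j, i] = network0.weights[i, j]
    return CoherenceNetwork(
        node_labels=labels,
        weights=out,
        stim_freq=network0.stim_freq,
        n_epochs_averaged=network0.n_epochs_averaged,
    )
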