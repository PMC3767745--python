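"""Correlation tables and the two-group edge-wise permutation test.

Pearson correlations (two-sided p from the t transform with n−2 degrees of
freedom) relate each network metric — and the mean connectivity — to the
subjects' stimulus-band SNRs.  Group differences in nodal connectivity are
assessed edge by edge with a permutation test: subjects are repeatedly
re-partitioned into two groups of the original sizes and the difference of
mean edge weights recomputed; the one-tailed p is the fraction of permuted
differences at least as extreme as the observed one, in the direction of
the observed sign.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .connectivity import CoherenceNetwork
from .graph_metrics import TopologyMetrics

__all__ = [
    "pearson",
    "pearson_vectorized",
    "metric_snr_correlations",
    "PermutationResult",
    "group_permutation_test",
    "METRIC_COLUMNS",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = (
    "mean_connectivity",
    "clustering",
    "path_length",
    "global_eff",
    "local_eff",
)


def pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p (t transform, n−2 df).

    Raises on length mismatch, n < 3, or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 observations, got {x.size}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values: Pearson correlation undefined")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: Pearson correlation undefined")
    res = sp_stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def pearson_vectorized(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r and two-sided p of ``X`` (n × m) against ``y``.

    Degenerate columns (zero variance in the column or in ``y``) yield
    ``r = nan, p = 1`` instead of raising, so callers can flag them.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError(f"X has {X.shape[0]} rows but y has {n} entries")
    if n < 3:
        raise ValueError(f"need at least 3 observations, got {n}")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc**2).sum(axis=0))
    sy = float(np.sqrt((yc**2).sum()))
    denom = sx * sy
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Xc * yc[:, None]).sum(axis=0) / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1e-300, 1.0 - r**2))
    p = 2.0 * sp_stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), 1.0, np.clip(p, 0.0, 1.0))
    return r, p


def metric_snr_correlations(
    metrics: list[TopologyMetrics],
    mean_connectivities: list[float] | np.ndarray,
    snrs: list[float] | np.ndarray,
    condition: str,
    network_id: int,
) -> pd.DataFrame:
    """Correlate each topology metric with SNR across subjects.

    ``metrics`` holds one :class:`TopologyMetrics` per subject (aligned with
    ``mean_connectivities`` and ``snrs``).  Returns one row per metric in
    ``METRIC_COLUMNS`` with columns (condition, network_id, metric, r, p, n).
    """
    snrs = np.asarray(snrs, dtype=float)
    if not len(metrics) == len(mean_connectivities) == snrs.size:
        raise ValueError(
            f"misaligned inputs: {len(metrics)} metrics, "
            f"{len(mean_connectivities)} connectivities, {snrs.size} SNRs"
        )
    values = {
        "mean_connectivity": [float(v) for v in mean_connectivities],
        "clustering": [tm.clustering for tm in metrics],
        "path_length": [tm.path_length for tm in metrics],
        "global_eff": [tm.global_eff for tm in metrics],
        "local_eff": [tm.local_eff for tm in metrics],
    }
    rows = []
    for metric in METRIC_COLUMNS:
        vec = np.asarray(values[metric])
        try:
            r, p = pearson(vec, snrs)
        except ValueError as exc:
            # Constant metric (e.g. no triangles in a sparse sub-network for
            # any subject) or NaN path lengths: report the row as undefined
            # rather than aborting the sweep.
            logger.warning("correlation undefined for %s: %s", metric, exc)
            r, p = float("nan"), float("nan")
        rows.append(
            dict(
                condition=condition,
                network_id=network_id,
                metric=metric,
                r=r,
                p=p,
                n=int(snrs.size),
            )
        )
    return pd.DataFrame(rows)


@dataclass
class PermutationResult:
    """Edge-wise two-group permutation test outcome."""

    edges: list[tuple[str, str]]
    #: Mean weight of group A minus mean weight of group B, per edge.
    observed_diff: np.ndarray
    #: One-tailed p per edge, tail following the sign of the observed diff.
    p: np.ndarray
    n_permutations: int
    seed: int | None
    method: str


def _edge_arrays(
    networksA: list[CoherenceNetwork],
    networksB: list[CoherenceNetwork],
) -> tuple[list[tuple[str, str]], np.ndarray, np.ndarray]:
    from .partition import edge_union, edge_weight_matrix

    edges = edge_union(networksA + networksB)
    WA = edge_weight_matrix(networksA, edges)
    WB = edge_weight_matrix(networksB, edges)
    return edges, WA, WB


def group_permutation_test(
    networksA: list[CoherenceNetwork],
    networksB: list[CoherenceNetwork],
    n_perm: int = 5000,
    seed: int | None = 0,
    method: str = "auto",
    exact_limit: int = 10_000,
) -> PermutationResult:
    """Edge-wise permutation test of mean connectivity between two groups.

    Edges are the union of both groups' Network-0 edge sets (absent edges
    weigh 0).  ``method='sampled'`` draws ``n_perm`` random re-partitions of
    the pooled subjects into groups of the original sizes and uses the
    add-one estimator p = (#extreme + 1) / (n_perm + 1); ``'exact'``
    enumerates every distinct split (e.g. the 70 splits of 4 + 4) and uses
    the raw proportion, which includes the identity split, so p ≥ 1/#splits.
    ``'auto'`` picks exact enumeration when the number of splits is at most
    ``exact_limit``.  In both modes p values are strictly positive.
    """
    if not networksA or not networksB:
        raise ValueError("both groups must be non-empty")
    nA, nB = len(networksA), len(networksB)
    if nA + nB < 2:
        raise ValueError("need at least 2 subjects in total")
    edges, WA, WB = _edge_arrays(networksA, networksB)
    observed = WA.mean(axis=0) - WB.mean(axis=0)
    pooled = np.concatenate([WA, WB], axis=0)
    n = nA + nB

    n_splits = math.comb(n, nA)
    if method == "auto":
        method = "exact" if n_splits <= exact_limit else "sampled"
    if method not in ("exact", "sampled"):
        raise ValueError(f"unknown method {method!r}")

    if method == "exact":
        diffs = np.empty((n_splits, len(edges)))
        all_idx = np.arange(n)
        for k, groupA in enumerate(itertools.combinations(range(n), nA)):
            maskA = np.zeros(n, dtype=bool)
            maskA[list(groupA)] = True
            diffs[k] = pooled[maskA].mean(axis=0) - pooled[all_idx[~maskA]].mean(axis=0)
        ge = (diffs >= observed).sum(axis=0)
        le = (diffs <= observed).sum(axis=0)
        p = np.where(observed >= 0, ge / n_splits, le / n_splits)
        return PermutationResult(edges, observed, p, n_splits, None, "exact")

    rng = np.random.default_rng(seed)
    count = np.zeros(len(edges))
    pos_tail = observed >= 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        dA = pooled[perm[:nA]].mean(axis=0) - pooled[perm[nA:]].mean(axis=0)
        count += np.where(pos_tail, dA >= observed, dA <= observed)
    p = (count + 1.0) / (n_perm + 1.0)
    return PermutationResult(edges, observed, p, n_perm, seed, "sampled")
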