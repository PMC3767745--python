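"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: clustering by explicit
triple loops, shortest paths by exhaustive simple-path enumeration, and the
efficiencies assembled from those paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def bf_degrees(w: np.ndarray) -> np.ndarray:
    return np.array([sum(1 for j in range(w.shape[0]) if w[i, j] > 0)
                     for i in range(w.shape[0])])


def bf_clustering(w: np.ndarray) -> tuple[np.ndarray, float]:
    n = w.shape[0]
    w_max = w.max()
    if w_max == 0:
        return np.zeros(n), 0.0
    w_hat = w / w_max
    per = np.zeros(n)
    for i in range(n):
        k = sum(1 for j in range(n) if w[i, j] > 0)
        if k < 2:
            continue
        total = 0.0
        for j in range(n):
            for h in range(n):
                if j == h or j == i or h == i:
                    continue
                total += (w_hat[i, j] * w_hat[i, h] * w_hat[j, h]) ** (1.0 / 3.0)
        per[i] = total / (k * (k - 1))
    return per, float(per.mean())


def bf_shortest_paths(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest path over lengths 1/w by simple-path enumeration."""
    n = w.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            others = [k for k in range(n) if k not in (i, j)]
            best = np.inf
            for r in range(len(others) + 1):
                for mid in itertools.permutations(others, r):
                    path = (i, *mid, j)
                    length = 0.0
                    ok = True
                    for a, b in zip(path[:-1], path[1:]):
                        if w[a, b] <= 0:
                            ok = False
                            break
                        length += 1.0 / w[a, b]
                    if ok:
                        best = min(best, length)
            dist[i, j] = best
    return dist


def bf_global_efficiency(w: np.ndarray) -> float:
    n = w.shape[0]
    dist = bf_shortest_paths(w)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(dist[i, j]):
                total += 1.0 / dist[i, j]
    return total / (n * (n - 1))


def bf_characteristic_path_length(w: np.ndarray) -> float:
    eff = bf_global_efficiency(w)
    return 1.0 / eff


def bf_local_efficiency(w: np.ndarray) -> tuple[np.ndarray, float]:
    n = w.shape[0]
    per = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = w[np.ix_(nb, nb)]
        per[i] = bf_global_efficiency(sub)
    return per, float(per.mean())
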