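"""Independent brute-force reference implementations used as test oracles.

These deliberately use different algorithms from the package (quadratic
broadcasting, Floyd-Warshall, explicit BFS expansion) so agreement is a
genuine cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


def sttc_brute(a: np.ndarray, b: np.ndarray, dt: float, duration: float) -> float:
    """STTC via O(n*m) pairwise comparison and explicit interval merging."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        return 0.0

    def tiled(t: np.ndarray) -> float:
        ivals = sorted((max(0.0, x - dt), min(duration, x + dt)) for x in t)
        total, cur_lo, cur_hi = 0.0, *ivals[0]
        for lo, hi in ivals[1:]:
            if lo > cur_hi:
                total += cur_hi - cur_lo
                cur_lo, cur_hi = lo, hi
            else:
                cur_hi = max(cur_hi, hi)
        total += cur_hi - cur_lo
        return total / duration

    def prop(x: np.ndarray, y: np.ndarray) -> float:
        return float(np.mean(np.any(np.abs(x[:, None] - y[None, :]) <= dt, axis=1)))

    ta, tb = tiled(a), tiled(b)
    pa, pb = prop(a, b), prop(b, a)
    terms = []
    if pa * tb != 1.0:
        terms.append((pa - tb) / (1.0 - pa * tb))
    if pb * ta != 1.0:
        terms.append((pb - ta) / (1.0 - pb * ta))
    return float(np.mean(terms)) if terms else 1.0


def dbscan_brute(dist: np.ndarray, eps: float, min_neighbors: int) -> int:
    """Cluster count of DBSCAN by explicit core-point BFS expansion.

    ``min_neighbors`` counts eps-neighbors excluding the point itself.
    Returns the number of clusters (noise excluded).
    """
    n = dist.shape[0]
    neighbors = [
        {j for j in range(n) if j != i and dist[i, j] <= eps} for i in range(n)
    ]
    core = [len(neighbors[i]) >= min_neighbors for i in range(n)]
    visited = [False] * n
    clusters = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        clusters += 1
        stack = [i]
        visited[i] = True
        while stack:
            p = stack.pop()
            if not core[p]:
                continue  # border point: joined but not expanded
            for q in neighbors[p]:
                if not visited[q]:
                    visited[q] = True
                    stack.append(q)
    return clusters


def graph_metrics_brute(adj: np.ndarray) -> tuple[float, float, float]:
    """(mean degree, mean clustering, global efficiency) via Floyd-Warshall."""
    n = adj.shape[0]
    deg = adj.sum(axis=1)
    clust = []
    for i in range(n):
        k = int(deg[i])
        if k < 2:
            clust.append(0.0)
            continue
        nbrs = np.nonzero(adj[i])[0]
        links = sum(
            adj[u, v] for ai, u in enumerate(nbrs) for v in nbrs[ai + 1 :]
        )
        clust.append(2.0 * links / (k * (k - 1)))
    d = np.where(adj > 0, 1.0, math.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    eff = inv.sum() / (n * (n - 1)) if n > 1 else 0.0
    return float(deg.mean()), float(np.mean(clust)), float(eff)


def poisson_tail(n: int, mu: float) -> float:
    """P(X >= n) for X ~ Poisson(mu) by direct summation."""
    if n <= 0:
        return 1.0
    # direct upper-tail sum (avoids 1 - CDF cancellation at extreme tails)
    log_term = -mu + n * math.log(mu) - math.lgamma(n + 1)
    term = math.exp(log_term)
    total = 0.0
    k = n
    while term > total * 1e-18 + 5e-324:
        total += term
        k += 1
        term *= mu / k
    return total


def davies_bouldin_brute(points: np.ndarray, labels: np.ndarray) -> float:
    """Davies-Bouldin from its definition, looping over cluster pairs."""
    uniq = sorted(set(labels.tolist()))
    cents = {u: points[labels == u].mean(axis=0) for u in uniq}
    scat = {
        u: float(np.mean(np.linalg.norm(points[labels == u] - cents[u], axis=1)))
        for u in uniq
    }
    total = 0.0
    for i in uniq:
        worst = 0.0
        for j in uniq:
            if i == j:
                continue
            dij = float(np.linalg.norm(cents[i] - cents[j]))
            ratio = (scat[i] + scat[j]) / dij if dij > 0 else math.inf
            worst = max(worst, ratio)
        total += worst
    return total / len(uniq)
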