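"""Independent brute-force oracles used to check the fast implementations.

These deliberately avoid the code paths they verify: distances, SSEs and
merge costs are recomputed directly from raw points.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def nan_distance(a: np.ndarray, b: np.ndarray, n_items: int = 8) -> float:
    """Rescaled Euclidean distance over mutually observed coordinates."""
    both = ~np.isnan(a) & ~np.isnan(b)
    if both.sum() == 0:
        return np.inf
    d2 = float(((a[both] - b[both]) ** 2).sum())
    return np.sqrt(n_items / both.sum() * d2)


def knn_impute_naive(X: np.ndarray, k: int) -> np.ndarray:
    """Literal nearest-neighbour mean imputation from first principles."""
    X = X.copy()
    n, p = X.shape
    filled = X.copy()
    for i in range(n):
        for j in range(p):
            if not np.isnan(X[i, j]):
                continue
            donors = [r for r in range(n) if r != i and not np.isnan(X[r, j])]
            donors.sort(key=lambda r: (nan_distance(X[i], X[r], p), r))
            chosen = donors[:k]
            filled[i, j] = np.mean([X[r, j] for r in chosen])
    return filled


def sse(points: np.ndarray) -> float:
    c = points.mean(axis=0)
    return float(((points - c) ** 2).sum())


def naive_ward_partitions(X: np.ndarray) -> dict[int, list[set[int]]]:
    """Greedy Ward agglomeration computed directly from point coordinates.

    At each step merges the pair of clusters with the smallest increase in
    total within-cluster SSE.  Returns the partition (as sets of row
    indices) at every cluster count k = n..1.
    """
    clusters: list[set[int]] = [{i} for i in range(len(X))]
    partitions = {len(clusters): [set(c) for c in clusters]}
    while len(clusters) > 1:
        best, best_pair = None, None
        for a, b in combinations(range(len(clusters)), 2):
            merged = clusters[a] | clusters[b]
            delta = (
                sse(X[sorted(merged)])
                - sse(X[sorted(clusters[a])])
                - sse(X[sorted(clusters[b])])
            )
            if best is None or delta < best:
                best, best_pair = delta, (a, b)
        a, b = best_pair
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
        partitions[len(clusters)] = [set(c) for c in clusters]
    return partitions


def labels_to_partition(labels: np.ndarray) -> list[set[int]]:
    return [set(np.flatnonzero(labels == lab)) for lab in np.unique(labels)]


def same_partition(p1: list[set[int]], p2: list[set[int]]) -> bool:
    return sorted(map(sorted, p1)) == sorted(map(sorted, p2))


def best_k_partition_sse(X: np.ndarray, k: int) -> float:
    """Minimum total within-SSE over all partitions into k non-empty blocks."""

    def partitions_into(items, k):
        if k == 1:
            yield [list(items)]
            return
        if len(items) == k:
            yield [[i] for i in items]
            return
        head, rest = items[0], items[1:]
        for part in partitions_into(rest, k):
            for i in range(len(part)):
                yield part[:i] + [part[i] + [head]] + part[i + 1:]
        for part in partitions_into(rest, k - 1):
            yield [[head]] + part

    return min(
        sum(sse(X[sorted(block)]) for block in part)
        for part in partitions_into(list(range(len(X))), k)
    )


def spearman_by_hand(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of average ranks, written out long-hand."""

    def avg_ranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v), dtype=float)
        ranks[order] = np.arange(1, len(v) + 1)
        for val in np.unique(v):
            ranks[v == val] = ranks[v == val].mean()
        return ranks

    rx, ry = avg_ranks(np.asarray(x, float)), avg_ranks(np.asarray(y, float))
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
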