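"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (naive O(n^3) loops,
full enumeration) and never calls the code paths it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def complete_linkage_bruteforce(dist: np.ndarray):
    """Naive complete-linkage agglomeration on a full distance matrix.

    Returns (heights in merge order, list of partitions after each merge,
    each partition a list of frozensets of leaf indices).
    """
    n = dist.shape[0]
    clusters: list[set[int]] = [{i} for i in range(n)]
    heights = []
    partitions = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
        heights.append(d)
        partitions.append([frozenset(c) for c in clusters])
    return np.array(heights), partitions


def cut_bruteforce(dist: np.ndarray, h: float):
    """Partition from the brute-force dendrogram cut at height h.

    Merges with height > h are discarded: replay merges while the next
    height is <= h.
    """
    heights, partitions = complete_linkage_bruteforce(dist)
    n = dist.shape[0]
    current = [frozenset({i}) for i in range(n)]
    for height, part in zip(heights, partitions):
        if height > h:
            break
        current = part
    labels = np.empty(n, dtype=int)
    for k, c in enumerate(current):
        for i in c:
            labels[i] = k
    return labels


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration over fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):  # x = top-left cell
        return (
            math.comb(r1, x) * math.comb(r2, c1 - x) / math.comb(n, c1)
        )

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(1.0, total)


def free_days_by_day_count(outcome_days: int, death_day: int | None, horizon: int = 28) -> int:
    """Count, day by day, the days inside the window not spent on the outcome."""
    window = horizon if death_day is None else min(horizon, death_day)
    return sum(1 for day in range(1, int(window) + 1) if day > outcome_days)


def nearest_centroid_labels(values: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Assign each row to the closest centroid (plain loop)."""
    labels = np.empty(values.shape[0], dtype=int)
    for i, row in enumerate(values):
        labels[i] = int(np.argmin([np.linalg.norm(row - c) for c in centroids]))
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two label vectors induce the same set partition."""
    pa = {}
    pb = {}
    for i, (x, y) in enumerate(zip(a, b)):
        pa.setdefault(x, set()).add(i)
        pb.setdefault(y, set()).add(i)
    return {frozenset(s) for s in pa.values()} == {frozenset(s) for s in pb.values()}
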