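"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: closure by
plain breadth-first search over a dict, Spearman as Pearson on hand-built
average ranks, Benjamini–Hochberg by direct formula, Mann–Whitney by full
enumeration of label assignments, and tissue-specificity by exhaustive
subset search.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def bfs_closure(children: dict[str, set[str]], seeds) -> set[str]:
    """Reflexive descendant closure by BFS over a child-adjacency dict."""
    out = set(seeds)
    queue = deque(seeds)
    while queue:
        node = queue.popleft()
        for child in children.get(node, ()):  # noqa: B909
            if child not in out:
                out.add(child)
                queue.append(child)
    return out


def average_ranks(values) -> list[float]:
    """1-based ranks with ties receiving the mean of their positions."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        mean_rank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mean_rank
        i = j + 1
    return ranks


def pearson(x, y) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def spearman_brute(x, y) -> float:
    """Spearman as Pearson of average ranks."""
    return pearson(average_ranks(list(x)), average_ranks(list(y)))


def bh_brute(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up by the direct formula."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        q = pvalues[i] * m / (rank_pos + 1)
        running_min = min(running_min, q)
        adjusted[i] = min(running_min, 1.0)
    return adjusted


def mwu_exact_brute(x, y) -> tuple[float, float]:
    """Exact two-sided Mann–Whitney by full enumeration (tie-free inputs).

    U counts pairs (xi, yj) with xi > yj. The p-value doubles the smaller
    tail of the exact null distribution over all label assignments, capped
    at 1.
    """
    x = list(x)
    y = list(y)
    u_obs = sum(1 for a in x for b in y if a > b)
    pooled = x + y
    n = len(x)
    dist: dict[int, int] = {}
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = sum(1 for a in xs for b in ys if a > b)
        dist[u] = dist.get(u, 0) + 1
        total += 1
    lower = sum(c for u, c in dist.items() if u <= u_obs) / total
    upper = sum(c for u, c in dist.items() if u >= u_obs) / total
    return float(u_obs), min(1.0, 2.0 * min(lower, upper))


def specificity_brute(levels: dict[str, float], fold: float = 4.0) -> tuple[str, tuple]:
    """Exhaustive-subset tissue-specificity classification.

    Checks every subset of size 1, then 2..5, against the maximum of the
    complement; returns the first (smallest) qualifying subset.
    """
    tissues = list(levels)
    if max(levels.values()) <= 0:
        return "not-specific", ()
    for size in range(1, min(5, len(tissues) - 1) + 1):
        hits = []
        for subset in itertools.combinations(tissues, size):
            rest = [levels[t] for t in tissues if t not in subset]
            mn = min(levels[t] for t in subset)
            if mn > 0 and mn >= fold * max(rest):
                hits.append(tuple(sorted(subset)))
        if hits:
            label = "tissue-enriched" if size == 1 else "group-enriched"
            return label, hits[0]
    return "not-specific", ()
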