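"""Brute-force DBSCAN written independently of the engine, for oracle checks.

Textbook formulation: core points have at least ``min_samples`` neighbors
within ``eps`` (self included); clusters are the connected components of the
core-point graph; border points join the cluster of the first core point
(in seed-expansion order) that reaches them; everything else is noise.
"""

from __future__ import annotations

from collections import deque


def brute_force_dbscan(dist: list[list[float]], eps: float,
                       min_samples: int) -> list[int]:
    n = len(dist)
    neighbors = [[j for j in range(n) if dist[i][j] <= eps] for i in range(n)]
    is_core = [len(neighbors[i]) >= min_samples for i in range(n)]
    labels = [-1] * n
    cluster = 0
    for seed in range(n):
        if labels[seed] != -1 or not is_core[seed]:
            continue
        queue = deque([seed])
        labels[seed] = cluster
        while queue:
            p = queue.popleft()
            if not is_core[p]:
                continue  # border points do not expand
            for q in neighbors[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    queue.append(q)
        cluster += 1
    return labels


def equivalent_labelings(a, b) -> bool:
    """True if two labelings agree up to a bijective renaming of cluster ids
    (noise, −1, must map to noise)."""
    if len(a) != len(b):
        return False
    fwd: dict[int, int] = {}
    rev: dict[int, int] = {}
    for x, y in zip(a, b):
        x, y = int(x), int(y)
        if (x == -1) != (y == -1):
            return False
        if x == -1:
            continue
        if fwd.setdefault(x, y) != y or rev.setdefault(y, x) != x:
            return False
    return True
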