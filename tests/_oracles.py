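"""Independent reference implementations used only as test oracles."""

from __future__ import annotations

import numpy as np


def brute_force_agglomerate(d: np.ndarray, names: list[str], linkage: str):
    """Naive O(N^3) agglomerative clustering, recomputing every
    inter-cluster distance from the original matrix at each step.

    Returns the set of (frozenset members, height) merges.  Distances for
    single/complete/average are min/max/mean over all original point pairs
    — no Lance-Williams recursion, so this is an independent route.
    """
    n = len(names)
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    merges: list[tuple[frozenset[str], float]] = []

    def cluster_dist(a: frozenset[int], b: frozenset[int]) -> float:
        vals = [d[i, j] for i in a for j in b]
        if linkage == "single":
            return min(vals)
        if linkage == "complete":
            return max(vals)
        if linkage == "average":
            return float(np.mean(vals))
        raise ValueError(linkage)

    while len(clusters) > 1:
        best = None
        for ai in range(len(clusters)):
            for bi in range(ai + 1, len(clusters)):
                dist = cluster_dist(clusters[ai], clusters[bi])
                na = min(names[i] for i in clusters[ai])
                nb = min(names[i] for i in clusters[bi])
                key = (dist, *sorted((na, nb)))
                if best is None or key < best[0]:
                    best = (key, ai, bi, dist)
        _, ai, bi, dist = best
        merged = clusters[ai] | clusters[bi]
        merges.append((frozenset(names[i] for i in merged), dist))
        clusters = [c for k, c in enumerate(clusters) if k not in (ai, bi)]
        clusters.append(merged)
    return merges


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    d = rng.uniform(0.5, 10.0, size=(n, n))
    d = np.triu(d, 1)
    return d + d.T
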