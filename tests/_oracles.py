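"""Independent brute-force oracles used only by the tests."""

from itertools import combinations
from math import comb

import numpy as np


def complete_linkage_two_clusters(X):
    """Naive agglomerative complete-linkage clustering cut into two
    clusters: repeatedly merge the pair of clusters with the smallest
    maximum pairwise Euclidean distance until two remain."""
    X = np.asarray(X, dtype=float)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = [frozenset([i]) for i in range(len(X))]
    while len(clusters) > 2:
        best = None
        for a, b in combinations(range(len(clusters)), 2):
            dist = max(D[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or dist < best[0]:
                best = (dist, a, b)
        _, a, b = best
        merged = clusters[a] | clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return frozenset(clusters)


def hypergeom_upper_tail(k, N, K, n):
    """P[X >= k] for X ~ Hypergeometric(N, K, n) by explicit enumeration."""
    denom = comb(N, n)
    lo = max(k, 0, n + K - N)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(lo, min(n, K) + 1)) / denom
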