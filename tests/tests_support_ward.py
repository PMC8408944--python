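"""Brute-force Ward-objective oracle shared by the waves tests."""

import numpy as np


def brute_force_ward(X: np.ndarray) -> list[frozenset]:
    """Greedy merges minimizing the increase in total within-cluster SS."""
    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []

    def ss(idx):
        pts = X[list(idx)]
        return ((pts - pts.mean(axis=0)) ** 2).sum()

    while len(clusters) > 1:
        best, best_cost = None, np.inf
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                cost = (
                    ss(clusters[i] | clusters[j])
                    - ss(clusters[i])
                    - ss(clusters[j])
                )
                if cost < best_cost - 1e-12:
                    best, best_cost = (i, j), cost
        i, j = best
        merged = clusters[i] | clusters[j]
        merges.append(merged)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return merges


def linkage_merges(Z: np.ndarray, n: int) -> list[frozenset]:
    """The cluster produced at each step of a scipy linkage matrix."""
    members = {i: frozenset([i]) for i in range(n)}
    merges = []
    for step, (a, b, _, _) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + step] = merged
        merges.append(merged)
    return merges
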