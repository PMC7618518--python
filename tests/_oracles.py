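"""Independent brute-force reference implementations used only by tests."""

import numpy as np


def dbscan_bruteforce(points, eps, min_pts):
    """O(n^2) DBSCAN: explicit neighbour matrix, BFS cluster expansion.

    Core point: >= min_pts neighbours within eps, itself included.
    Border points join the first core cluster that reaches them.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    neigh = d <= eps
    core = neigh.sum(axis=1) >= min_pts
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cid
        while queue:
            j = queue.pop()
            if not core[j]:
                continue
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    queue.append(k)
        cid += 1
    return labels


def labels_equivalent(a, b):
    """Label equality up to permutation (noise label -1 fixed)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or np.any((a == -1) != (b == -1)):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


def ripley_k_naive(points, radii, area):
    """Double-loop evaluation of K(r) = A/(n(n-1)) sum_{i!=j} 1(d_ij<=r)."""
    points = np.asarray(points, dtype=float)
    n = len(points)
    k = np.zeros(len(radii))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            dij = np.hypot(*(points[i] - points[j]))
            k += dij <= np.asarray(radii)
    return area * k / (n * (n - 1))
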