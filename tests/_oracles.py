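"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from first principles (explicit
loops, direct formulas, generalized-eigenvalue routes) and stays independent
of the code paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.special import betainc


def hd_weights_direct(n: int, q: float) -> np.ndarray:
    """HD beta weights via an explicit per-order-statistic loop."""
    a = (n + 1) * q
    b = (n + 1) * (1 - q)
    w = np.empty(n)
    for i in range(1, n + 1):
        w[i - 1] = betainc(a, b, i / n) - betainc(a, b, (i - 1) / n)
    return w


def hd_quantile_direct(x, q: float) -> float:
    xs = np.sort(np.asarray(x, dtype=float))
    return float(hd_weights_direct(len(xs), q) @ xs)


def ward_linkage_brute(X: np.ndarray):
    """Greedy agglomerative Ward via the Lance-Williams update.

    Returns (heights, merges) where merges is the list of member-index sets
    merged at each step, in merge order.  Distances are maintained as
    squared Euclidean cluster distances; the reported height is the square
    root at merge time (the same convention scipy's ward linkage uses).
    """
    n = len(X)
    active = list(range(n))
    sizes = {i: 1 for i in range(n)}
    members = {i: frozenset([i]) for i in range(n)}
    D2 = {}
    for i in range(n):
        for j in range(i + 1, n):
            D2[(i, j)] = float(((X[i] - X[j]) ** 2).sum())

    def d2(a, b):
        return D2[(a, b) if a < b else (b, a)]

    heights, merges, snapshots = [], [], []
    nxt = n
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                if best is None or d2(a, b) < best[0]:
                    best = (d2(a, b), a, b)
        dmin, s, t = best
        heights.append(np.sqrt(dmin))
        new_members = members[s] | members[t]
        merges.append(new_members)
        for v in active:
            if v in (s, t):
                continue
            num = (
                (sizes[v] + sizes[s]) * d2(v, s)
                + (sizes[v] + sizes[t]) * d2(v, t)
                - sizes[v] * dmin
            )
            D2[(v, nxt) if v < nxt else (nxt, v)] = num / (
                sizes[v] + sizes[s] + sizes[t]
            )
        sizes[nxt] = sizes[s] + sizes[t]
        members[nxt] = new_members
        active = [v for v in active if v not in (s, t)] + [nxt]
        snapshots.append([members[v] for v in active])
        nxt += 1
    return np.array(heights), merges, snapshots


def ward_partition_brute(X: np.ndarray, k: int) -> set[frozenset]:
    """Partition into k clusters from the brute-force agglomeration."""
    _, _, snapshots = ward_linkage_brute(X)
    n = len(X)
    # snapshot after merge m has n - 1 - m clusters
    return set(snapshots[n - 1 - k])


def partition_from_labels(labels) -> set[frozenset]:
    labels = np.asarray(labels)
    return {
        frozenset(np.nonzero(labels == c)[0].tolist()) for c in np.unique(labels)
    }


def canonical_correlations_eig(Xa: np.ndarray, Xb: np.ndarray) -> np.ndarray:
    """Canonical correlations via the generalized-eigenvalue route.

    Eigenvalues of Saa^{-1} Sab Sbb^{-1} Sba are the squared canonical
    correlations.
    """
    A = np.asarray(Xa, float)
    B = np.asarray(Xb, float)
    A = (A - A.mean(0)) / A.std(0, ddof=1)
    B = (B - B.mean(0)) / B.std(0, ddof=1)
    n = A.shape[0]
    Saa = A.T @ A / (n - 1)
    Sbb = B.T @ B / (n - 1)
    Sab = A.T @ B / (n - 1)
    M = np.linalg.inv(Saa) @ Sab @ np.linalg.inv(Sbb) @ Sab.T
    ev = np.linalg.eigvals(M)
    ev = np.sort(np.real(ev))[::-1]
    return np.sqrt(np.clip(ev, 0, 1))


def variance_decomposition_brute(X: np.ndarray, labels) -> tuple[float, float]:
    """Within/between percentages by direct sums of squares."""
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    total = ((X - grand) ** 2).sum()
    within = 0.0
    between = 0.0
    for c in np.unique(labels):
        rows = X[labels == c]
        within += ((rows - rows.mean(axis=0)) ** 2).sum()
        between += len(rows) * ((rows.mean(axis=0) - grand) ** 2).sum()
    return 100 * within / total, 100 * between / total
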