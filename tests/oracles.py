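"""Independent brute-force oracles used only by the test suite.

These deliberately re-implement the contracts with the simplest possible
algorithms (O(n^2) scans, exhaustive enumeration) so they share no code with
the package implementations they check.
"""

import numpy as np


def brute_force_merge(points: np.ndarray, mpt: float):
    """Reference blink merge: repeatedly combine the globally closest pair
    with separation <= mpt (ties by lowest id pair); merged nodes sit at the
    centroid of their original constituent blinks.

    Returns (positions sorted by smallest member id, member index lists).
    """
    points = np.asarray(points, dtype=float)
    nodes = {i: [i] for i in range(len(points))}
    next_id = len(points)

    def pos(members):
        return points[members].mean(axis=0)

    while True:
        best = None
        ids = sorted(nodes)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = float(np.linalg.norm(pos(nodes[a]) - pos(nodes[b])))
                if d <= mpt and (best is None or (d, a, b) < best):
                    best = (d, a, b)
        if best is None:
            break
        _, a, b = best
        nodes[next_id] = sorted(nodes[a] + nodes[b])
        del nodes[a], nodes[b]
        next_id += 1

    members = sorted(nodes.values(), key=lambda m: m[0])
    return np.array([pos(m) for m in members]), members


def set_partitions(n: int):
    """All partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i, max_label):
        if i == n:
            yield labels.copy()
            return
        for v in range(max_label + 2):
            labels[i] = v
            yield from rec(i + 1, max(max_label, v))

    yield from rec(0, -1)


def exhaustive_max_modularity(W: np.ndarray):
    """Maximum Newman modularity over every partition (feasible for n <= 8)."""
    W = np.asarray(W, dtype=float)
    n = len(W)
    two_m = W.sum()
    k = W.sum(axis=1)
    best_q, best_p = -np.inf, None
    for part in set_partitions(n):
        q = 0.0
        for c in np.unique(part):
            idx = part == c
            q += W[np.ix_(idx, idx)].sum() / two_m - (k[idx].sum() / two_m) ** 2
        if q > best_q:
            best_q, best_p = q, part
    return best_q, best_p
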