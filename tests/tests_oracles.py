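"""Independent brute-force oracles shared by the acceptance tests.

These deliberately avoid the package's own algorithms: the UPGMA oracle
is a naive O(n^3) agglomeration, the split oracle an O(n^2 p) exhaustive
scan sharing only the documented tie-break convention.
"""

import numpy as np


def brute_force_upgma(d: np.ndarray) -> np.ndarray:
    """Naive average-linkage agglomeration; returns cophenetic distances."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    dist = {frozenset((i, j)): d[i, j] for i in range(n) for j in range(i + 1, n)}
    coph = np.zeros((n, n))
    next_id = n
    while len(clusters) > 1:
        pair = min(dist, key=lambda k: (dist[k], sorted(k)))
        h = dist[pair]
        a, b = sorted(pair)
        members_a, members_b = clusters.pop(a), clusters.pop(b)
        for i in members_a:
            for j in members_b:
                coph[i, j] = coph[j, i] = h
        merged = members_a + members_b
        for c in clusters:
            da = dist.pop(frozenset((a, c)))
            db = dist.pop(frozenset((b, c)))
            dist[frozenset((next_id, c))] = (len(members_a) * da + len(members_b) * db) / len(merged)
        dist.pop(pair)
        clusters[next_id] = merged
        next_id += 1
    return coph


def _ss(y):
    y = np.asarray(y, dtype=float)
    return ((y - y.mean(axis=0)) ** 2).sum()


def exhaustive_best_split(X, y, minbucket=1):
    """Exhaustive single-split search: max dSS, then widest log-scale gap,
    then lowest feature index, then lowest threshold."""
    n, p = X.shape
    best = None
    for j in range(p):
        xs = np.sort(np.unique(X[:, j]))
        for lo, hi in zip(xs[:-1], xs[1:]):
            thr = (lo + hi) / 2
            mask = X[:, j] < thr
            if mask.sum() < minbucket or (~mask).sum() < minbucket:
                continue
            dss = _ss(y) - _ss(y[mask]) - _ss(y[~mask])
            gap = np.log(hi / lo) if lo > 0 else hi - lo
            cand = (dss, gap, -j, -thr)
            if best is None or (cand[0] > best[0] + 1e-9) or (
                abs(cand[0] - best[0]) <= 1e-9 and cand[1:] > best[1:]
            ):
                best = cand
    if best is None:
        return None
    return -best[2], -best[3], best[0]
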