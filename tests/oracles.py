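"""Independent brute-force oracles used to check the package implementations.

Everything here is deliberately naive: BFS flood fill, exhaustive cube
enumeration with plain loops, and full enumeration of sign/label assignments
for the rank tests. None of it shares code with the package.
"""

import itertools
from collections import deque

import numpy as np


def bfs_component(values, seed, threshold):
    """26-connected component of {v > threshold} containing seed, by BFS."""
    seed = tuple(seed)
    shape = values.shape
    if not values[seed] > threshold:
        return set()
    seen = {seed}
    queue = deque([seed])
    while queue:
        p = queue.popleft()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for dk in (-1, 0, 1):
                    if di == dj == dk == 0:
                        continue
                    q = (p[0] + di, p[1] + dj, p[2] + dk)
                    if (
                        all(0 <= q[a] < shape[a] for a in range(3))
                        and q not in seen
                        and values[q] > threshold
                    ):
                        seen.add(q)
                        queue.append(q)
    return seen


def match_volume_oracle(values, seed, target_volume_cm3, spacing):
    """Globally optimal threshold VOI by evaluating every unique voxel value.

    Returns (threshold, voxel set). Ties in |dV| go to the larger volume
    (lower threshold).
    """
    seed = tuple(seed)
    vox_cm3 = float(np.prod(spacing)) / 1000.0
    target_n = target_volume_cm3 / vox_cm3
    best = None
    for t in np.unique(values):
        if not values[seed] > t:
            continue
        comp = bfs_component(values, seed, t)
        err = abs(len(comp) - target_n)
        if best is None or err < best[0] - 1e-12 or (
            abs(err - best[0]) <= 1e-12 and len(comp) > len(best[2])
        ):
            best = (err, t, comp)
    return best[1], best[2]


def peak_oracle(values, spacing, voi_set, edge_mm=10.0):
    """Exhaustive max-mean cube search over all center-in-VOI placements."""
    shape = values.shape
    dims = [max(1, int(np.floor(edge_mm / s + 0.5))) for s in spacing]
    best = -np.inf
    for c in sorted(voi_set):
        acc, cnt = 0.0, 0
        for a in range(c[0] - (dims[0] - 1) // 2, c[0] - (dims[0] - 1) // 2 + dims[0]):
            for b in range(c[1] - (dims[1] - 1) // 2, c[1] - (dims[1] - 1) // 2 + dims[1]):
                for d in range(c[2] - (dims[2] - 1) // 2, c[2] - (dims[2] - 1) // 2 + dims[2]):
                    if 0 <= a < shape[0] and 0 <= b < shape[1] and 0 <= d < shape[2]:
                        acc += values[a, b, d]
                        cnt += 1
        best = max(best, acc / cnt)
    return best


def _rank(values):
    """Average ranks, naive O(n^2)."""
    values = list(values)
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def wilcoxon_oracle(differences):
    """Two-sided exact p by enumerating all 2^n sign assignments."""
    d = [x for x in differences if x != 0]
    n = len(d)
    ranks = _rank([abs(x) for x in d])
    w_obs = sum(r for r, x in zip(ranks, d) if x > 0)
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product((0, 1), repeat=n)
    ]
    total = float(len(ws))
    cdf = sum(1 for w in ws if w <= w_obs + 1e-12) / total
    sf = sum(1 for w in ws if w >= w_obs - 1e-12) / total
    return w_obs, min(1.0, 2.0 * min(cdf, sf))


def mannwhitney_oracle(group_a, group_b, alternative="two-sided"):
    """Exact p by enumerating all C(m+n, m) label assignments."""
    a, b = list(group_a), list(group_b)
    m = len(a)
    combined = a + b

    def u_stat(sel):
        ga = [combined[i] for i in sel]
        gb = [combined[i] for i in range(len(combined)) if i not in sel]
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in ga for y in gb
        )

    u_obs = sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b)
    us = [u_stat(set(sel)) for sel in itertools.combinations(range(len(combined)), m)]
    total = float(len(us))
    sf = sum(1 for u in us if u >= u_obs - 1e-12) / total
    if alternative == "greater":
        return u_obs, sf
    cdf = sum(1 for u in us if u <= u_obs + 1e-12) / total
    return u_obs, min(1.0, 2.0 * min(cdf, sf))
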