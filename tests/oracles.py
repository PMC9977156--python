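"""Independent oracles used by the test suite.

These deliberately avoid the algorithms used by the package:

* ``chain_local_align_score`` scores local alignments as chains of matched
  residue pairs (an O(n^2 m^2) recurrence over predecessor pairs with whole
  gap runs costed in one step), never the three-state affine DP used by
  production aligners.
* ``exact_ranksum_p`` enumerates every assignment of the pooled sample to
  the two groups and computes the two-sided tail probability of the
  Mann-Whitney U statistic directly.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def chain_local_align_score(query: str, target: str,
                            gap_open: int = 11, gap_extend: int = 1) -> float:
    """Best local alignment score as a max-weight chain of matched pairs.

    A gap of length k costs gap_open + k * gap_extend; adjacent gap runs in
    the two sequences are costed independently.
    """

    def gap_cost(dq: int, dt: int) -> float:
        cost = 0.0
        if dq > 0:
            cost += gap_open + dq * gap_extend
        if dt > 0:
            cost += gap_open + dt * gap_extend
        return cost

    n, m = len(query), len(target)
    best = 0.0
    f = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            prev = 0.0
            for i2 in range(i):
                row = f[i2]
                for j2 in range(j):
                    cand = row[j2] - gap_cost(i - i2 - 1, j - j2 - 1)
                    if cand > prev:
                        prev = cand
            f[i][j] = float(_B62[query[i]][target[j]]) + prev
            if f[i][j] > best:
                best = f[i][j]
    return best


def _u_statistic(xs, ys) -> float:
    u = 0.0
    for a in xs:
        for b in ys:
            if a > b:
                u += 1.0
            elif a == b:
                u += 0.5
    return u


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group
    assignments of the pooled sample."""
    x, y = list(x), list(y)
    n = len(x)
    pooled = x + y
    u_obs = _u_statistic(x, y)
    us = []
    idx = set(range(len(pooled)))
    for comb in combinations(range(len(pooled)), n):
        chosen = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx - chosen]
        us.append(_u_statistic(xs, ys))
    us = np.asarray(us)
    p_le = float(np.mean(us <= u_obs + 1e-9))
    p_ge = float(np.mean(us >= u_obs - 1e-9))
    return min(1.0, 2.0 * min(p_le, p_ge))


def overlap_components(intervals) -> list[set[int]]:
    """Connected components of the interval-overlap graph, by brute-force
    pairwise comparison (oracle for transitive overlap merging)."""
    n = len(intervals)
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            (ci, si, ei), (cj, sj, ej) = intervals[i], intervals[j]
            if ci == cj and si < ej and sj < ei:
                parent[find(i)] = find(j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
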