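"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation paths they verify: naive
union-find instead of scipy hierarchical clustering, a hand-coded BH
step-up, direct enumeration for the exact Kruskal-Wallis permutation null.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def brute_force_clones(records, threshold):
    """All-pairs single-linkage partition: union cells with same V gene,
    J gene, junction length and normalized Hamming distance <= threshold."""
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    rows = records.to_dict("records")
    for i in range(n):
        for j in range(i + 1, n):
            a, b = rows[i], rows[j]
            if a["v_call"].split("*")[0] != b["v_call"].split("*")[0]:
                continue
            if a["j_call"].split("*")[0] != b["j_call"].split("*")[0]:
                continue
            ja, jb = a["junction"], b["junction"]
            if len(ja) != len(jb):
                continue
            d = sum(x != y for x, y in zip(ja, jb)) / len(ja)
            if d <= threshold:
                union(i, j)
    return [find(i) for i in range(n)]


def partitions_equal(labels_a, labels_b) -> bool:
    """Two labelings induce the same partition."""
    map_ab, map_ba = {}, {}
    for a, b in zip(labels_a, labels_b):
        if map_ab.setdefault(a, b) != b:
            return False
        if map_ba.setdefault(b, a) != a:
            return False
    return True


def bh_stepup(pvals, alpha=0.05):
    """Hand-coded Benjamini-Hochberg adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adj[i] = running_min
    return adj


def exact_kruskal_p(groups):
    """Exact permutation p-value of the Kruskal-Wallis H over all
    assignments of the pooled values to the given group sizes."""
    values = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in values]
    pooled = np.concatenate(values)
    n = pooled.size

    def h_stat(assignment):
        gs = [pooled[list(ix)] for ix in assignment]
        return stats.kruskal(*gs).statistic

    obs = stats.kruskal(*values).statistic
    count = total = 0
    idx = list(range(n))
    for first in itertools.combinations(idx, sizes[0]):
        rest1 = [i for i in idx if i not in first]
        for second in itertools.combinations(rest1, sizes[1]):
            third = tuple(i for i in rest1 if i not in second)
            total += 1
            if h_stat((first, second, third)) >= obs - 1e-12:
                count += 1
    return count / total


def hill_numeric_limit(proportions, eps=1e-6):
    """D(1) via the numerical q -> 1 limit (average of q = 1 +/- eps)."""
    p = np.asarray(proportions, dtype=float)
    p = p[p > 0]

    def d(q):
        return np.sum(p ** q) ** (1.0 / (1.0 - q))

    return 0.5 * (d(1 - eps) + d(1 + eps))
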