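"""Independent brute-force reference implementations used only by tests.

These deliberately follow the written definitions step by step (quadruple
loops, explicit set algebra, textbook DBSCAN) and share no code with the
package's optimized implementations.
"""

from __future__ import annotations

import math

from scipy.stats import chi2


def brute_support_sets(input_pl, root_pl, stds, tolerance_units, mode):
    """O(n^4) support matrix: SS[(i,j)] = {(m,n): concordant within the
    per-dimension tolerance box}, with the self-mode exclusions."""
    ni, nr = len(input_pl), len(root_pl)
    dims_in = input_pl.comparable_dims
    dims_root = root_pl.comparable_dims
    ss = {}
    for i in range(ni):
        for j in range(nr):
            if mode == "self" and i == j:
                continue
            members = set()
            for m in range(ni):
                for n in range(nr):
                    if (m, n) == (i, j):
                        continue
                    if mode == "self" and m == n:
                        continue
                    ok = True
                    for l, (di, dr) in enumerate(zip(dims_in, dims_root)):
                        a = input_pl[i].shifts[di] - input_pl[m].shifts[di]
                        b = root_pl[j].shifts[dr] - root_pl[n].shifts[dr]
                        if abs(a - b) > tolerance_units * stds[l]:
                            ok = False
                            break
                    if ok:
                        members.add((m, n))
            ss[(i, j)] = members
    return ss


def brute_chi_prob(input_pl, root_pl, i, j, m, n, stds, std_factor):
    dims_in = input_pl.comparable_dims
    dims_root = root_pl.comparable_dims
    stat = 0.0
    for l, (di, dr) in enumerate(zip(dims_in, dims_root)):
        a = input_pl[i].shifts[di] - input_pl[m].shifts[di]
        b = root_pl[j].shifts[dr] - root_pl[n].shifts[dr]
        stat += ((a - b) / (stds[l] * std_factor)) ** 2
    return float(chi2.sf(stat, len(dims_in)))


def brute_robustness(ss, input_pl, root_pl, i, j, stds, std_factor):
    """Direct summation of the Jaccard-weighted, chi-square-weighted
    robustness score over the support set of (i, j)."""
    members = ss.get((i, j), set())
    total = 0.0
    for m, n in members:
        other = ss.get((m, n), set())
        inter = len(members & other)
        union = len(members | other)
        jac = inter / union if union else 0.0
        total += jac * brute_chi_prob(input_pl, root_pl, i, j, m, n, stds, std_factor)
    return total


def brute_dbscan(points, eps, min_points):
    """Textbook DBSCAN over a list of coordinate tuples with plain Euclidean
    distance; returns (labels, n_clusters) with label -1 for noise.  Points
    are visited in index order and the region query includes the point."""
    n = len(points)

    def dist(a, b):
        return math.sqrt(sum((x - y) ** 2 for x, y in zip(points[a], points[b])))

    def region(p):
        return [q for q in range(n) if dist(p, q) <= eps]

    labels = [None] * n  # None = unvisited, -1 = noise
    cid = -1
    for p in range(n):
        if labels[p] is not None:
            continue
        neighbors = region(p)
        if len(neighbors) < min_points:
            labels[p] = -1
            continue
        cid += 1
        labels[p] = cid
        seeds = list(neighbors)
        k = 0
        while k < len(seeds):
            q = seeds[k]
            k += 1
            if labels[q] == -1:
                labels[q] = cid  # border point
            if labels[q] is not None:
                continue
            labels[q] = cid
            q_neighbors = region(q)
            if len(q_neighbors) >= min_points:
                seeds.extend(q_neighbors)
    return labels, cid + 1
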