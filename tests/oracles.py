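"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written in the most literal way possible
(explicit loops, no vectorisation, no shared helpers with the package) so
that agreement with the package is a meaningful check.
"""

from __future__ import annotations

import math


def brute_count_contacts(points_a, points_b, cutoff):
    """Number of (a, b) pairs within the cutoff: all-pairs O(n^2) scan."""
    count = 0
    for pa in points_a:
        for pb in points_b:
            d = math.dist(tuple(pa), tuple(pb))
            if d <= cutoff:
                count += 1
    return count


def brute_min_dist(points_a, points_b):
    best = float("inf")
    for pa in points_a:
        for pb in points_b:
            best = min(best, math.dist(tuple(pa), tuple(pb)))
    return best


def brute_quality_filter(loops, resolution_max, bfactor_max):
    """Literal re-statement of the loop quality rules."""
    kept = []
    for loop in loops:
        if loop.resolution is None:
            continue
        if loop.resolution > resolution_max:
            continue
        if loop.missing_residues:
            continue
        if loop.max_backbone_bfactor >= bfactor_max:
            continue
        kept.append(loop)
    return kept


def brute_dtw(trace_a, trace_b):
    """DTW-RMSD by exhaustive enumeration of all monotone warp paths.

    Feasible for traces of length <= ~7.  The score is
    sqrt(total / path_length) for the lexicographically smallest
    (total, path_length) over all paths.
    """
    n, m = len(trace_a), len(trace_b)

    def d2(i, j):
        return sum((trace_a[i][k] - trace_b[j][k]) ** 2 for k in range(3))

    best = [None]

    def walk(i, j, total, steps):
        total = total + d2(i, j)
        steps += 1
        if i == n - 1 and j == m - 1:
            cand = (total, steps)
            if best[0] is None or cand < best[0]:
                best[0] = cand
            return
        for ni, nj in ((i + 1, j + 1), (i + 1, j), (i, j + 1)):
            if ni < n and nj < m:
                walk(ni, nj, total, steps)

    walk(0, 0, 0.0, 0)
    total, steps = best[0]
    return math.sqrt(total / steps)


def brute_rmsd(coords_a, coords_b):
    assert len(coords_a) == len(coords_b)
    s = 0.0
    for pa, pb in zip(coords_a, coords_b):
        s += sum((pa[k] - pb[k]) ** 2 for k in range(3))
    return math.sqrt(s / len(coords_a))


def brute_dbscan(dist, eps, min_pts):
    """Textbook DBSCAN on a precomputed distance matrix.

    Returns labels with -1 for noise; cluster ids follow discovery order
    over points in index order.
    """
    n = len(dist)
    UNVISITED, NOISE = None, -1
    labels = [UNVISITED] * n

    def neighbours(i):
        return [j for j in range(n) if dist[i][j] <= eps]

    cluster = -1
    for i in range(n):
        if labels[i] is not UNVISITED:
            continue
        nbs = neighbours(i)
        if len(nbs) < min_pts:
            labels[i] = NOISE
            continue
        cluster += 1
        labels[i] = cluster
        seeds = [j for j in nbs if j != i]
        k = 0
        while k < len(seeds):
            j = seeds[k]
            k += 1
            if labels[j] == NOISE:
                labels[j] = cluster
            if labels[j] is not UNVISITED:
                continue
            labels[j] = cluster
            j_nbs = neighbours(j)
            if len(j_nbs) >= min_pts:
                for q in j_nbs:
                    if q not in seeds:
                        seeds.append(q)
    return labels


def same_partition(labels_a, labels_b, noise_a=-1, noise_b=-1):
    """True when two labelings induce the same partition (noise matched)."""
    if len(labels_a) != len(labels_b):
        return False
    mapping = {}
    reverse = {}
    for la, lb in zip(labels_a, labels_b):
        if (la == noise_a) != (lb == noise_b):
            return False
        if la == noise_a:
            continue
        if mapping.setdefault(la, lb) != lb:
            return False
        if reverse.setdefault(lb, la) != la:
            return False
    return True


def brute_torsion_deg(u, axis, v):
    """Signed dihedral oracle using the atan2 formulation."""
    def cross(a, b):
        return (
            a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0],
        )

    def dot(a, b):
        return sum(x * y for x, y in zip(a, b))

    def norm(a):
        return math.sqrt(dot(a, a))

    n = norm(axis)
    ax = tuple(x / n for x in axis)
    x = dot(cross(cross(u, ax), cross(ax, v)), ax)
    # standard atan2 dihedral: y = (u x ax) . (ax x v), x-part scaled
    up = tuple(ui - dot(u, ax) * ai for ui, ai in zip(u, ax))
    vp = tuple(vi - dot(v, ax) * ai for vi, ai in zip(v, ax))
    y = dot(cross(up, vp), ax)
    c = dot(up, vp)
    return math.degrees(math.atan2(y, c))
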