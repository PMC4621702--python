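"""Independent oracles for the clustering algorithms.

``reference_dp_means`` is a literal, numpy-free transcription of the
distance-threshold DP-means pass structure, kept deliberately naive so it can
serve as an independent check of the production implementation.

``valid_medoid_partitions`` enumerates every set partition of a small item
set and returns those satisfying the fixed-point conditions of the medoid
variant: each cluster's medoid (member minimising the within-cluster
dissimilarity sum, ties toward the lowest index) is within lambda of all
members, and no item is strictly closer to another cluster's medoid than to
its own.
"""

from __future__ import annotations

import math


def reference_dp_means(points, lam, max_passes=100):
    """Return the partition as a set of frozensets of point indices."""
    n = len(points)
    centres: list[list[float]] = []
    assign: list[int | None] = [None] * n
    for _ in range(max_passes):
        changed = False
        for i in range(n):
            best_j = None
            best_d = None
            for j, c in enumerate(centres):
                d = math.dist(points[i], c)
                if best_d is None or d < best_d:
                    best_j, best_d = j, d
            if best_d is None or best_d > lam:
                centres.append(list(points[i]))
                best_j = len(centres) - 1
            if assign[i] != best_j:
                assign[i] = best_j
                changed = True
        new_centres = []
        remap = {}
        for k in range(len(centres)):
            members = [i for i in range(n) if assign[i] == k]
            if members:
                remap[k] = len(new_centres)
                dim = len(points[0])
                new_centres.append(
                    [
                        sum(points[i][axis] for i in members) / len(members)
                        for axis in range(dim)
                    ]
                )
        assign = [remap[a] for a in assign]
        centres = new_centres
        if not changed:
            break
    groups: dict[int, list[int]] = {}
    for i, a in enumerate(assign):
        groups.setdefault(a, []).append(i)
    return {frozenset(g) for g in groups.values()}


def _set_partitions(items):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for k in range(len(partition)):
            yield partition[:k] + [partition[k] + [first]] + partition[k + 1:]
        yield partition + [[first]]


def _medoid(D, members):
    best, best_sum = None, None
    for i in sorted(members):
        s = sum(D[i][j] for j in members)
        if best_sum is None or s < best_sum:
            best, best_sum = i, s
    return best


def valid_medoid_partitions(D, lam):
    """All fixed-point partitions of the medoid DP-means conditions."""
    n = len(D)
    valid = []
    for partition in _set_partitions(list(range(n))):
        medoids = [_medoid(D, cluster) for cluster in partition]
        ok = True
        for cluster, med in zip(partition, medoids):
            if any(D[i][med] > lam for i in cluster):
                ok = False
                break
        if not ok:
            continue
        for cluster, med in zip(partition, medoids):
            for i in cluster:
                if any(D[i][m] < D[i][med] for m in medoids):
                    ok = False
                    break
            if not ok:
                break
        if ok:
            valid.append({frozenset(c) for c in partition})
    return valid
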