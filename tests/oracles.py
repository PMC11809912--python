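"""Independent brute-force oracles the implementation is checked against.

Everything here is written from first principles — exhaustive pairwise
distances, breadth-first search, literal summation formulas — and shares
no code path with the package.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def brute_knn(pool: np.ndarray, query_index: int, k: int) -> list[int]:
    """k nearest rows by exhaustive distance sort; ties to the lower row id."""
    dists = []
    for i, row in enumerate(pool):
        if i == query_index:
            continue
        dists.append((math.dist(row, pool[query_index]), i, i))
    dists.sort()
    return [i for _, _, i in dists[:k]]


def bfs_dbscan(data: np.ndarray, eps: float, min_samples: int):
    """Role + cluster assignment via literal definitions and BFS.

    Returns (roles, clusters) with roles in {"core","border","noise"} and
    cluster -1 for noise. Clusters are connected components of core
    points (within eps of each other), found by BFS, numbered by lowest
    member row; border points attach to the nearest core's cluster with
    ties to the lower cluster id.
    """
    n = len(data)
    neighbors = [
        [j for j in range(n) if math.dist(data[i], data[j]) <= eps] for i in range(n)
    ]
    core = [len(neighbors[i]) >= min_samples for i in range(n)]
    roles = ["noise"] * n
    clusters = [-1] * n

    # BFS over core points only
    comp = [-1] * n
    n_comp = 0
    for start in range(n):
        if not core[start] or comp[start] != -1:
            continue
        queue = deque([start])
        comp[start] = n_comp
        while queue:
            u = queue.popleft()
            for v in neighbors[u]:
                if core[v] and comp[v] == -1:
                    comp[v] = n_comp
                    queue.append(v)
        n_comp += 1
    # renumber components by lowest row index
    first_row = {}
    for i in range(n):
        if core[i] and comp[i] not in first_row:
            first_row[comp[i]] = i
    renumber = {old: rank for rank, old in enumerate(sorted(first_row, key=first_row.get))}
    for i in range(n):
        if core[i]:
            roles[i] = "core"
            clusters[i] = renumber[comp[i]]

    for i in range(n):
        if core[i]:
            continue
        reachable = [j for j in neighbors[i] if core[j]]
        if not reachable:
            continue
        best = min(math.dist(data[i], data[j]) for j in reachable)
        candidate_clusters = [
            clusters[j] for j in reachable if math.dist(data[i], data[j]) == best
        ]
        roles[i] = "border"
        clusters[i] = min(candidate_clusters)
    return roles, clusters


def brute_tomek(features: np.ndarray, labels) -> set[tuple[int, int]]:
    """Mutual opposite-class 1-NN pairs by exhaustive search."""
    n = len(features)
    nn = []
    for i in range(n):
        best = min(
            (math.dist(features[i], features[j]), j) for j in range(n) if j != i
        )
        nn.append(best[1])
    return {
        (i, nn[i])
        for i in range(n)
        if nn[i] > i and nn[nn[i]] == i and labels[i] != labels[nn[i]]
    }


def brute_enn_keep(features: np.ndarray, labels, k: int) -> list[bool]:
    """Keep mask from literal neighbor voting (ties count as disagreement)."""
    n = len(features)
    keep = []
    for i in range(n):
        dists = sorted(
            (math.dist(features[i], features[j]), j, j) for j in range(n) if j != i
        )
        votes = {}
        for _, _, j in dists[:k]:
            votes[labels[j]] = votes.get(labels[j], 0) + 1
        own = votes.get(labels[i], 0)
        keep.append(all(own > v for lab, v in votes.items() if lab != labels[i]))
    return keep


def brute_kappa(table: np.ndarray) -> float:
    """Cohen's kappa straight from the summation definition."""
    table = np.asarray(table, dtype=float)
    total = table.sum()
    p_o = np.trace(table) / total
    p_e = sum(table[i, :].sum() * table[:, i].sum() for i in range(len(table))) / total**2
    return (p_o - p_e) / (1 - p_e) if p_e != 1 else 0.0


def brute_multiclass_mcc(table: np.ndarray) -> float:
    """Multiclass correlation coefficient from the covariance summations."""
    table = np.asarray(table, dtype=float)
    m = len(table)
    # cov(X, Y) over the indicator representation
    num = 0.0
    for k in range(m):
        for l in range(m):
            for mm in range(m):
                num += table[k, k] * table[l, mm] - table[k, l] * table[mm, k]
    den1 = 0.0
    den2 = 0.0
    for k in range(m):
        row_k = table[k, :].sum()
        other_rows = sum(table[kp, :].sum() for kp in range(m) if kp != k)
        den1 += row_k * other_rows
        col_k = table[:, k].sum()
        other_cols = sum(table[:, kp].sum() for kp in range(m) if kp != k)
        den2 += col_k * other_cols
    den = math.sqrt(den1) * math.sqrt(den2)
    return num / den if den != 0 else 0.0
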