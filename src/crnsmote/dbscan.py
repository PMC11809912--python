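"""Density-based clustering with explicit core/border/noise roles.

A point is *core* when its closed eps-ball (self included) holds at least
``min_samples`` points, *border* when it is not core but lies within eps
of a core point, and *noise* otherwise. Clusters are the connected
components of core points under the "within eps of each other" relation;
border points are attached to the cluster of their nearest core point
(ties to the lower cluster id) and counted as cluster members. Noise
points belong to no cluster.

The K-distance heuristic for choosing eps (a quantile of the distances
from each point to its k-th nearest neighbor) is also provided; the
fixed-eps RN-SMOTE baseline uses it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist

__all__ = [
    "CORE",
    "BORDER",
    "NOISE",
    "DbscanParams",
    "DbscanLabels",
    "region_query",
    "dbscan",
    "count_clusters",
    "kdistance_eps",
]

CORE = "core"
BORDER = "border"
NOISE = "noise"


@dataclass(frozen=True)
class DbscanParams:
    """Neighborhood radius eps and minimum neighborhood size (self included)."""

    eps: float
    min_samples: int = 5

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass(frozen=True)
class DbscanLabels:
    """Per-point role (core/border/noise) and cluster id (-1 for noise).

    Cluster ids are consecutive from 0, numbered by the lowest row index
    each cluster contains, so the labeling is deterministic.
    """

    role: np.ndarray  # str array
    cluster: np.ndarray  # int array, -1 = no cluster

    def __post_init__(self) -> None:
        role = np.asarray(self.role)
        cluster = np.asarray(self.cluster, dtype=int)
        if role.shape != cluster.shape:
            raise ValueError("role and cluster must have the same length")
        object.__setattr__(self, "role", role)
        object.__setattr__(self, "cluster", cluster)

    @property
    def noise_mask(self) -> np.ndarray:
        return self.role == NOISE

    @property
    def kept_mask(self) -> np.ndarray:
        return self.role != NOISE


def region_query(point_index: int, data: np.ndarray, eps: float) -> np.ndarray:
    """All row ids within Euclidean distance <= eps of the query, itself included."""
    data = np.asarray(data, dtype=float)
    dists = np.linalg.norm(data - data[point_index], axis=1)
    return np.flatnonzero(dists <= eps)


def dbscan(data: np.ndarray, params: DbscanParams) -> DbscanLabels:
    """Classify every point and partition core/border points into clusters."""
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n == 0:
        raise ValueError("dbscan needs at least one point")

    d = cdist(data, data)
    within = d <= params.eps
    counts = within.sum(axis=1)  # self included (distance 0)
    core = counts >= params.min_samples

    role = np.full(n, NOISE, dtype=object)
    cluster = np.full(n, -1, dtype=int)
    role[core] = CORE

    core_idx = np.flatnonzero(core)
    if core_idx.size:
        # connected components of the core graph
        adj = csr_matrix(within[np.ix_(core_idx, core_idx)])
        _, comp = connected_components(adj, directed=False)
        # renumber components by lowest global row index
        order = {}
        for local, row in enumerate(core_idx):
            comp_id = comp[local]
            if comp_id not in order:
                order[comp_id] = row
            else:
                order[comp_id] = min(order[comp_id], row)
        ranked = sorted(order, key=order.get)
        renumber = {old: new for new, old in enumerate(ranked)}
        cluster[core_idx] = [renumber[c] for c in comp]

        # border points: non-core within eps of a core; nearest core wins,
        # equal distances resolved toward the lower cluster id
        non_core = np.flatnonzero(~core)
        if non_core.size:
            dist_to_core = d[np.ix_(non_core, core_idx)]
            reachable = dist_to_core <= params.eps
            for pos, row in enumerate(non_core):
                hit = np.flatnonzero(reachable[pos])
                if hit.size == 0:
                    continue
                dd = dist_to_core[pos, hit]
                best = hit[dd == dd.min()]
                role[row] = BORDER
                cluster[row] = int(min(cluster[core_idx[b]] for b in best))

    return DbscanLabels(role=role, cluster=cluster)


def count_clusters(labels: DbscanLabels) -> int:
    """Number of distinct cluster ids, noise excluded."""
    ids = labels.cluster[labels.cluster >= 0]
    return int(np.unique(ids).size)


def kdistance_eps(data: np.ndarray, k: int, quantile: float = 0.90) -> float:
    """K-distance eps heuristic: a quantile of the k-th nearest-neighbor distances.

    For each point the distances to all points (self at distance 0
    included) are sorted and the k-th smallest among the others is taken;
    the requested quantile of those n values (linear interpolation
    between order statistics) is returned.
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} points, got {n}")
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    d = np.sort(cdist(data, data), axis=1)
    kth = d[:, k]  # column 0 is the self distance
    return float(np.quantile(kth, quantile))
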