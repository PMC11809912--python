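"""SMOTE synthetic minority oversampling.

New minority samples are linear interpolations x + beta * (neighbor - x)
between a randomly chosen minority sample and a randomly chosen member of
its K nearest same-class neighbors (Euclidean distance), with beta drawn
uniformly from [0, 1) for each synthetic point. Generation repeats per
class until every class reaches the target count (the majority count by
default).

By default the neighbor graph is computed once over the original minority
samples, so synthetic points never become parents — the canonical SMOTE
behavior. Setting ``grow_pool=True`` lets each inserted synthetic sample
join the candidate pool for subsequent draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .data import LabeledDataset, partition_by_class

__all__ = ["SmoteConfig", "SmoteAuditRecord", "interpolate", "minority_neighbors", "smote_balance"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SmoteConfig:
    """Tunables of the oversampling loop.

    k_neighbors : number of same-class nearest neighbors a parent is drawn
        from (K_SMOTE; the evaluation grid uses 4, 5 and 6).
    seed : seed for the single generator threading all random draws.
    target_count : per-class count to reach; defaults to the majority
        count. Classes already at or above the target are left unchanged.
    grow_pool : literal-insertion variant where synthetic samples join the
        neighbor pool as they are generated.
    """

    k_neighbors: int = 5
    seed: int = 0
    target_count: int | None = None
    grow_pool: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_count is not None and self.target_count < 1:
            raise ValueError("target_count must be positive")


@dataclass(frozen=True)
class SmoteAuditRecord:
    """Provenance of one synthetic sample (both parents are original rows
    unless ``grow_pool`` was set)."""

    label: str
    parent_a: int  # row id in the output dataset
    parent_b: int
    beta: float
    row: int  # row id of the synthetic sample in the output dataset


def interpolate(x: np.ndarray, neighbor: np.ndarray, beta: float) -> np.ndarray:
    """Return x + beta * (neighbor - x); each coordinate lies between the parents'."""
    x = np.asarray(x, dtype=float)
    neighbor = np.asarray(neighbor, dtype=float)
    if x.shape != neighbor.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {neighbor.shape}")
    if not 0.0 <= beta <= 1.0:
        raise ValueError(f"beta must be in [0, 1], got {beta}")
    return x + beta * (neighbor - x)


def minority_neighbors(index: int, pool: np.ndarray, k: int) -> np.ndarray:
    """Row ids of the k nearest pool rows to ``pool[index]``, excluding itself.

    Euclidean distance; ties break to the lower row id. When the pool has
    fewer than k + 1 rows, k is reduced to pool size - 1 with a warning.
    """
    pool = np.asarray(pool, dtype=float)
    n = pool.shape[0]
    if n < 2:
        raise ValueError("neighbor pool needs at least 2 rows")
    if k > n - 1:
        logger.warning("k=%d too large for pool of %d rows; using k=%d", k, n, n - 1)
        k = n - 1
    dists = np.linalg.norm(pool - pool[index], axis=1)
    order = np.argsort(dists, kind="stable")  # stable: ties keep lower row id first
    order = order[order != index]
    return order[:k]


def smote_balance(
    dataset: LabeledDataset,
    config: SmoteConfig = SmoteConfig(),
    return_audit: bool = False,
):
    """Oversample every below-target class to the target count.

    Original rows are preserved verbatim and first; synthetic rows are
    appended, carrying their class label. Classes are processed in sorted
    label order and all random draws come from one generator seeded with
    ``config.seed``, so identical inputs give identical outputs.

    Returns the balanced dataset, or ``(dataset, audit)`` when
    ``return_audit`` is true, where ``audit`` lists each synthetic row's
    parents and interpolation weight.
    """
    part = partition_by_class(dataset)
    target = config.target_count if config.target_count is not None else part.majority_count
    rng = np.random.default_rng(config.seed)

    new_rows: list[np.ndarray] = []
    new_labels: list[str] = []
    audit: list[SmoteAuditRecord] = []
    next_row = dataset.n_samples

    for cls in part.classes:  # sorted order
        deficit = target - part.counts[cls]
        if deficit <= 0:
            continue
        cls_idx = part.indices[cls]
        if cls_idx.size < 2:
            raise ValueError(
                f"class {cls!r} has {cls_idx.size} sample(s); SMOTE needs at least 2"
            )
        pool = dataset.features[cls_idx]
        pool_rows = list(cls_idx)  # output row ids of pool members
        k = min(config.k_neighbors, pool.shape[0] - 1)
        if k < config.k_neighbors:
            logger.warning(
                "class %r: k_neighbors reduced from %d to %d (class size %d)",
                cls, config.k_neighbors, k, pool.shape[0],
            )
        if not config.grow_pool:
            # one k-NN table over the original class samples
            d = cdist(pool, pool)
            np.fill_diagonal(d, np.inf)
            # stable argsort => distance ties resolved toward lower row id
            neighbor_table = np.argsort(d, axis=1, kind="stable")[:, :k]

        for _ in range(deficit):
            m = pool.shape[0]
            h = int(rng.integers(m))
            if config.grow_pool:
                dists = np.linalg.norm(pool - pool[h], axis=1)
                order = np.argsort(dists, kind="stable")
                order = order[order != h]
                kk = min(k, m - 1)
                neighbors = order[:kk]
            else:
                neighbors = neighbor_table[h]
            j = int(neighbors[int(rng.integers(len(neighbors)))])
            beta = float(rng.random())
            syn = interpolate(pool[h], pool[j], beta)
            new_rows.append(syn)
            new_labels.append(cls)
            audit.append(
                SmoteAuditRecord(
                    label=cls,
                    parent_a=int(pool_rows[h]),
                    parent_b=int(pool_rows[j]),
                    beta=beta,
                    row=next_row,
                )
            )
            if config.grow_pool:
                pool = np.vstack([pool, syn])
                pool_rows.append(next_row)
            next_row += 1

    if new_rows:
        features = np.vstack([dataset.features, np.asarray(new_rows)])
        labels = np.concatenate([dataset.labels, np.asarray(new_labels, dtype=str)])
        out = replace(dataset, features=features, labels=labels)
    else:
        out = dataset
    return (out, audit) if return_audit else out
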