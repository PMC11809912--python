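"""Resampling pipelines for imbalanced tabular data.

All four pipelines start by SMOTE-balancing every class to the majority
count and then clean up the synthetic-plus-original sample cloud:

* :func:`crn_smote` — per minority class, DBSCAN noise removal where the
  radius eps starts small (eps0) and grows by delta until the surviving
  points of the class form at most ``n_cluster`` clusters (and at least
  one). The idea is that the samples of one category should occupy one
  or two concentrated clusters; removing noise must not shatter a class.
  After the constrained cleanup, SMOTE runs once more to restore balance.
* :func:`rn_smote` — same three stages but with a single fixed-eps DBSCAN
  pass per class (eps from the K-distance heuristic when "auto") and no
  constraint on how many clusters survive.
* :func:`smote_tomek` — SMOTE then removal of Tomek links (mutual
  opposite-class nearest-neighbor pairs).
* :func:`smote_enn` — SMOTE then edited-nearest-neighbours filtering.

The majority class is never denoised by crn_smote/rn_smote: its rows pass
through unchanged and set the balance target for the final stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .data import LabeledDataset, partition_by_class
from .dbscan import DbscanParams, count_clusters, dbscan, kdistance_eps
from .smote import SmoteConfig, smote_balance

__all__ = [
    "CrnConfig",
    "ClassAudit",
    "ResampleResult",
    "adaptive_denoise_class",
    "crn_smote",
    "rn_smote",
    "tomek_links",
    "smote_tomek",
    "enn_filter",
    "smote_enn",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrnConfig:
    """Tunables of the cluster-constrained pipeline.

    n_cluster : largest acceptable number of clusters per class after
        noise removal (1 or 2 in practice — same-category samples should
        form one or two concentrated clusters).
    eps0 : initial DBSCAN radius, meaningful on [0, 1]-normalized
        features (default 0.1).
    delta : radius increment per iteration (default 0.05; at most ~20
        steps span a unit-scaled feature space).
    min_samples : DBSCAN core threshold N, self included (default 5).
    k_smote : SMOTE neighbor count for stages 1 and 3.
    seed : pipeline seed; stage 1 uses ``seed`` and stage 3 ``seed + 1``
        so the stages are independently reproducible.
    max_eps : radius guard; defaults to the class's max pairwise distance
        plus delta, where a single cluster is guaranteed.
    max_iter : iteration guard for the eps loop.
    """

    n_cluster: int = 1
    eps0: float = 0.1
    delta: float = 0.05
    min_samples: int = 5
    k_smote: int = 5
    seed: int = 0
    max_eps: float | None = None
    max_iter: int = 1000
    grow_pool: bool = False

    def __post_init__(self) -> None:
        if self.eps0 <= 0 or self.delta <= 0:
            raise ValueError("eps0 and delta must be positive")
        if self.n_cluster < 1:
            raise ValueError("n_cluster must be >= 1")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


@dataclass(frozen=True)
class ClassAudit:
    """What stage 2 and stage 3 did to one non-majority class."""

    label: str
    filtered: bool  # False when the class was passed through unfiltered
    final_eps: float | None
    n_clusters: int | None
    n_removed: int
    n_regenerated: int
    eps_trajectory: tuple[float, ...] = ()
    cluster_trajectory: tuple[int, ...] = ()


@dataclass(frozen=True)
class ResampleResult:
    """Balanced dataset plus the per-class audit trail."""

    data: LabeledDataset
    per_class: dict[str, ClassAudit]
    method: str

    def audit_dict(self) -> dict:
        """JSON-ready audit (per-class eps trajectory, cluster and removal counts)."""
        return {
            "method": self.method,
            "class_counts": self.data.class_counts(),
            "per_class": {
                label: {
                    "filtered": a.filtered,
                    "final_eps": a.final_eps,
                    "n_clusters": a.n_clusters,
                    "n_removed": a.n_removed,
                    "n_regenerated": a.n_regenerated,
                    "eps_trajectory": list(a.eps_trajectory),
                    "cluster_trajectory": list(a.cluster_trajectory),
                }
                for label, a in self.per_class.items()
            },
        }


def adaptive_denoise_class(
    samples: np.ndarray, config: CrnConfig
) -> tuple[np.ndarray, float | None, int | None, tuple[float, ...], tuple[int, ...]]:
    """Grow eps until the class's non-noise points form 0 < c <= n_cluster clusters.

    Runs DBSCAN at eps = eps0, eps0 + delta, ... and stops at the first
    radius whose cluster count satisfies the bound; the non-noise points
    at that radius are returned together with the final eps, the final
    cluster count and the full (eps, cluster-count) trajectory.
    Termination is guaranteed for classes of at least ``min_samples``
    points: once eps reaches the class diameter every point is core and
    exactly one cluster remains. Smaller classes are returned unchanged
    with a warning, since every point stays noise at every radius.
    """
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if n < config.min_samples:
        logger.warning(
            "class of %d samples is below min_samples=%d; passed through unfiltered",
            n, config.min_samples,
        )
        return samples, None, None, (), ()

    max_eps = config.max_eps
    if max_eps is None:
        diameter = float(pdist(samples).max()) if n > 1 else 0.0
        max_eps = diameter + config.delta

    eps = config.eps0
    eps_seen: list[float] = []
    clusters_seen: list[int] = []
    for _ in range(config.max_iter):
        labels = dbscan(samples, DbscanParams(eps=eps, min_samples=config.min_samples))
        c = count_clusters(labels)
        eps_seen.append(eps)
        clusters_seen.append(c)
        if 0 < c <= config.n_cluster:
            kept = samples[labels.kept_mask]
            return kept, eps, c, tuple(eps_seen), tuple(clusters_seen)
        if eps > max_eps:
            break
        eps = eps + config.delta

    logger.warning(
        "adaptive denoise exhausted (eps=%.4g, max_eps=%.4g, %d iterations) "
        "without satisfying the cluster bound; class passed through unfiltered",
        eps, max_eps, len(eps_seen),
    )
    return samples, None, None, tuple(eps_seen), tuple(clusters_seen)


def _three_stage(
    dataset: LabeledDataset,
    k_smote: int,
    seed: int,
    denoise,  # (class_label, class_matrix) -> (kept, audit fields...)
    method: str,
    grow_pool: bool = False,
) -> ResampleResult:
    """Shared SMOTE -> per-class denoise -> SMOTE skeleton of crn/rn pipelines."""
    part = partition_by_class(dataset)
    if len(part.classes) < 2:
        raise ValueError("resampling needs at least 2 classes")
    target = part.majority_count
    majority = part.majority

    stage1 = smote_balance(
        dataset, SmoteConfig(k_neighbors=k_smote, seed=seed, grow_pool=grow_pool)
    )

    blocks: list[np.ndarray] = [dataset.features[part.indices[majority]]]
    labels: list[np.ndarray] = [dataset.labels[part.indices[majority]]]
    audits: dict[str, ClassAudit] = {}
    kept_counts: dict[str, int] = {}
    for cls in part.minority_classes():
        cls_matrix = stage1.class_matrix(cls)
        kept, final_eps, n_clusters, eps_traj, cl_traj, filtered = denoise(cls, cls_matrix)
        if kept.shape[0] < 2:
            # stage-3 SMOTE needs >= 2 parents per class
            logger.warning(
                "class %r: denoising left %d point(s); passed through unfiltered",
                cls, kept.shape[0],
            )
            kept, final_eps, n_clusters, filtered = cls_matrix, None, None, False
        blocks.append(kept)
        labels.append(np.full(kept.shape[0], cls, dtype=object).astype(str))
        kept_counts[cls] = kept.shape[0]
        audits[cls] = ClassAudit(
            label=cls,
            filtered=filtered,
            final_eps=final_eps,
            n_clusters=n_clusters,
            n_removed=int(cls_matrix.shape[0] - kept.shape[0]),
            n_regenerated=0,  # filled after stage 3
            eps_trajectory=eps_traj,
            cluster_trajectory=cl_traj,
        )

    cleaned = LabeledDataset(
        features=np.vstack(blocks),
        labels=np.concatenate(labels),
        feature_names=dataset.feature_names,
        label_name=dataset.label_name,
    )
    stage3 = smote_balance(
        cleaned,
        SmoteConfig(
            k_neighbors=k_smote, seed=seed + 1, target_count=target, grow_pool=grow_pool
        ),
    )
    final_counts = stage3.class_counts()
    for cls, audit in audits.items():
        audits[cls] = ClassAudit(
            **{**audit.__dict__, "n_regenerated": final_counts[cls] - kept_counts[cls]}
        )
    return ResampleResult(data=stage3, per_class=audits, method=method)


def crn_smote(dataset: LabeledDataset, config: CrnConfig = CrnConfig()) -> ResampleResult:
    """Cluster-constrained three-stage resampling.

    Stage 1 SMOTE-balances every class to the majority count; stage 2
    applies :func:`adaptive_denoise_class` to each SMOTEd non-majority
    class (the majority rows pass through untouched); stage 3 SMOTEs the
    concatenation back to the original majority count.
    """

    def denoise(cls, matrix):
        kept, eps, c, eps_traj, cl_traj = adaptive_denoise_class(matrix, config)
        return kept, eps, c, eps_traj, cl_traj, eps is not None

    return _three_stage(
        dataset, config.k_smote, config.seed, denoise,
        method=f"{config.n_cluster}crn_smote", grow_pool=config.grow_pool,
    )


def rn_smote(
    dataset: LabeledDataset,
    k_smote: int = 5,
    dbscan_params: DbscanParams | str = "auto",
    seed: int = 0,
    min_samples: int = 5,
    kdistance_quantile: float = 0.90,
) -> ResampleResult:
    """Fixed-eps three-stage resampling (no cluster-count constraint).

    Stage 2 runs one standard DBSCAN per non-majority class and keeps the
    non-noise points of every cluster. With ``dbscan_params="auto"`` each
    class gets its own eps from the K-distance heuristic (k = min_samples,
    0.90 quantile).
    """

    def denoise(cls, matrix):
        if isinstance(dbscan_params, str):
            if dbscan_params != "auto":
                raise ValueError(f"unknown dbscan_params {dbscan_params!r}")
            if matrix.shape[0] <= min_samples:
                logger.warning(
                    "class %r too small for the K-distance heuristic; unfiltered", cls
                )
                return matrix, None, None, (), (), False
            eps = kdistance_eps(matrix, k=min_samples, quantile=kdistance_quantile)
            if eps <= 0:  # duplicate-heavy class: every k-th distance zero
                return matrix, None, None, (), (), False
            params = DbscanParams(eps=eps, min_samples=min_samples)
        else:
            params = dbscan_params
        if matrix.shape[0] < params.min_samples:
            logger.warning("class %r below min_samples; unfiltered", cls)
            return matrix, None, None, (), (), False
        labels = dbscan(matrix, params)
        c = count_clusters(labels)
        kept = matrix[labels.kept_mask]
        return kept, params.eps, c, (params.eps,), (c,), True

    return _three_stage(dataset, k_smote, seed, denoise, method="rn_smote")


def tomek_links(dataset: LabeledDataset) -> set[tuple[int, int]]:
    """All (i, j), i < j, of opposite class that are mutual nearest neighbors.

    Nearest neighbors are computed over the whole dataset (any class),
    excluding self; distance ties break to the lower row id.
    """
    part = partition_by_class(dataset)
    if len(part.classes) < 2:
        raise ValueError("tomek_links needs at least 2 classes")
    d = cdist(dataset.features, dataset.features)
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)  # argmin returns the first (lowest id) minimizer
    links = set()
    for i in range(dataset.n_samples):
        j = int(nn[i])
        if j > i and int(nn[j]) == i and dataset.labels[i] != dataset.labels[j]:
            links.add((i, j))
    return links


def smote_tomek(
    dataset: LabeledDataset,
    k_smote: int = 5,
    seed: int = 0,
    removal: str = "both",
) -> ResampleResult:
    """SMOTE to balance, then delete Tomek-link members as boundary noise.

    ``removal="both"`` (default) removes both ends of every link;
    ``"majority"`` removes only the majority-class member. Class counts
    may end unequal.
    """
    if removal not in ("both", "majority"):
        raise ValueError(f"unknown removal policy {removal!r}")
    part = partition_by_class(dataset)
    balanced = smote_balance(dataset, SmoteConfig(k_neighbors=k_smote, seed=seed))
    links = tomek_links(balanced)
    drop: set[int] = set()
    for i, j in links:
        if removal == "both":
            drop.update((i, j))
        else:
            for r in (i, j):
                if balanced.labels[r] == part.majority:
                    drop.add(r)
    keep = np.array([r for r in range(balanced.n_samples) if r not in drop], dtype=int)
    out = balanced.subset(keep)
    removed_per_class: dict[str, int] = {c: 0 for c in part.classes}
    for r in drop:
        removed_per_class[str(balanced.labels[r])] += 1
    audits = {
        cls: ClassAudit(
            label=cls, filtered=True, final_eps=None, n_clusters=None,
            n_removed=removed_per_class[cls], n_regenerated=0,
        )
        for cls in part.classes
    }
    return ResampleResult(data=out, per_class=audits, method="smote_tomek")


def enn_filter(dataset: LabeledDataset, k: int = 3) -> LabeledDataset:
    """Edited nearest neighbours: drop samples out-voted by their k neighbors.

    A sample survives only when its own label is the strict majority among
    its k nearest neighbors (self excluded, distance ties to the lower
    row id); vote ties count as disagreement.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = dataset.n_samples
    if n <= k:
        raise ValueError(f"need more than k={k} samples, got {n}")
    d = cdist(dataset.features, dataset.features)
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    keep = np.zeros(n, dtype=bool)
    for i in range(n):
        votes: dict[str, int] = {}
        for j in order[i]:
            lab = str(dataset.labels[j])
            votes[lab] = votes.get(lab, 0) + 1
        own = votes.get(str(dataset.labels[i]), 0)
        keep[i] = all(own > v for lab, v in votes.items() if lab != str(dataset.labels[i]))
    return dataset.subset(np.flatnonzero(keep))


def smote_enn(
    dataset: LabeledDataset, k_smote: int = 5, seed: int = 0, k_enn: int = 3
) -> ResampleResult:
    """SMOTE to balance, then ENN filtering with k = 3 by default."""
    part = partition_by_class(dataset)
    balanced = smote_balance(dataset, SmoteConfig(k_neighbors=k_smote, seed=seed))
    filtered = enn_filter(balanced, k=k_enn)
    before = balanced.class_counts()
    after = filtered.class_counts()
    audits = {
        cls: ClassAudit(
            label=cls, filtered=True, final_eps=None, n_clusters=None,
            n_removed=before.get(cls, 0) - after.get(cls, 0), n_regenerated=0,
        )
        for cls in part.classes
    }
    return ResampleResult(data=filtered, per_class=audits, method="smote_enn")
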