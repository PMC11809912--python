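"""Seeded generators for imbalanced tabular test data.

Datasets are Gaussian-mixture blobs: each class draws its samples around
one or two centers with a configurable spread, optionally replacing a
fraction of its rows with points scattered uniformly over the feature
box. Those uniform points emulate outliers/mislabeled samples — the
failure mode SMOTE amplifies and density-based noise removal targets.
Class counts are honored exactly and everything is deterministic in the
seed.

:func:`make_maternal_like` reproduces the shape of a 3-class
1014-sample maternal-health-risk benchmark (406/336/272) whose diffuse,
overlapping minority classes fragment into many small clusters under a
small-radius DBSCAN — the pathology that motivates constraining the
cluster count during noise removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset

__all__ = ["ClassSpec", "GeneratorSpec", "make_imbalanced", "make_maternal_like", "BENCHMARK_SHAPES"]

# class-count shapes of the four UCI benchmarks the pipelines are aimed at
BENCHMARK_SHAPES: dict[str, tuple[int, ...]] = {
    "qsar": (699, 356),
    "blood": (570, 178),
    "ilpd": (416, 167),
    "maternal": (406, 336, 272),
}


@dataclass(frozen=True)
class ClassSpec:
    """One class of a synthetic dataset.

    centers holds 1 or 2 component means (each of length n_features); a
    two-center class exercises the N_cluster = 2 regime. spread is the
    isotropic standard deviation of each Gaussian component.
    """

    label: str
    count: int
    centers: tuple[tuple[float, ...], ...]
    spread: float = 0.05

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("class count must be >= 1")
        if not 1 <= len(self.centers) <= 2:
            raise ValueError("a class needs 1 or 2 centers")
        if self.spread <= 0:
            raise ValueError("spread must be positive")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of a synthetic imbalanced dataset."""

    class_specs: tuple[ClassSpec, ...]
    n_features: int
    noise_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.class_specs:
            raise ValueError("need at least one class")
        if not 0 <= self.noise_fraction < 1:
            raise ValueError("noise_fraction must be in [0, 1)")
        for spec in self.class_specs:
            for center in spec.centers:
                if len(center) != self.n_features:
                    raise ValueError(
                        f"class {spec.label!r}: center has {len(center)} coordinates, "
                        f"expected {self.n_features}"
                    )


def _feature_box(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Bounding box spanning every center +- 3 spreads, shared by all noise points."""
    centers = np.array([c for s in spec.class_specs for c in s.centers], dtype=float)
    pad = 3.0 * max(s.spread for s in spec.class_specs)
    return centers.min(axis=0) - pad, centers.max(axis=0) + pad


def make_imbalanced(spec: GeneratorSpec) -> LabeledDataset:
    """Draw the dataset described by ``spec``.

    Per class, ``round(noise_fraction * count)`` rows are replaced (not
    added) by uniform draws over the shared feature box while keeping the
    class's label, so requested counts hold exactly and the noise rows
    look like outliers or mislabeled points.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = _feature_box(spec)
    features: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for cls in spec.class_specs:
        n_noise = int(round(spec.noise_fraction * cls.count))
        n_clean = cls.count - n_noise
        # deal clean points across components round-robin (equal halves up to 1)
        per_component = [
            n_clean // len(cls.centers) + (1 if i < n_clean % len(cls.centers) else 0)
            for i in range(len(cls.centers))
        ]
        rows = [
            rng.normal(loc=center, scale=cls.spread, size=(m, spec.n_features))
            for center, m in zip(cls.centers, per_component)
            if m > 0
        ]
        if n_noise:
            rows.append(rng.uniform(lo, hi, size=(n_noise, spec.n_features)))
        features.append(np.vstack(rows) if rows else np.empty((0, spec.n_features)))
        labels.append(np.full(cls.count, cls.label, dtype=object))
    return LabeledDataset(
        features=np.vstack(features),
        labels=np.concatenate(labels).astype(str),
        feature_names=tuple(f"f{i}" for i in range(spec.n_features)),
        label_name="label",
    )


def make_benchmark_like(name: str, seed: int = 0, n_features: int = 8,
                        noise_fraction: float = 0.05, spread: float = 0.07,
                        separation: float = 0.35) -> LabeledDataset:
    """A dataset with the class counts of one of the four UCI benchmarks.

    Classes sit at single centers ``separation`` apart along rotating
    axes of a unit-scaled feature space, with ``noise_fraction`` of each
    class replaced by uniform box points.
    """
    counts = BENCHMARK_SHAPES[name]
    if name == "maternal":
        return make_maternal_like(seed=seed)
    specs = []
    for i, count in enumerate(counts):
        center = np.full(n_features, 0.5)
        center[i % n_features] += separation * (1 if i % 2 == 0 else -1)
        center[(i + 1) % n_features] -= separation * 0.5
        specs.append(
            ClassSpec(label=f"c{i + 1}", count=count, centers=(tuple(center),), spread=spread)
        )
    return make_imbalanced(
        GeneratorSpec(
            class_specs=tuple(specs),
            n_features=n_features,
            noise_fraction=noise_fraction,
            seed=seed,
        )
    )


def make_maternal_like(seed: int = 0) -> LabeledDataset:
    """Three classes sized 406/336/272 whose minorities fragment under DBSCAN.

    The two minority classes are diffuse two-component mixtures that
    overlap each other heavily, plus 5% uniform noise. At a small radius
    (eps = 0.1 on this unit-scaled 2-D space, min_samples = 5) standard
    DBSCAN splits them into several small clusters; growing the radius
    under the cluster-count constraint merges them back into one or two.
    """
    specs = (
        ClassSpec(label="c1", count=406, centers=((0.10, 0.90),), spread=0.06),
        ClassSpec(
            label="c2", count=336,
            centers=((0.45, 0.45), (0.75, 0.25)), spread=0.30,
        ),
        ClassSpec(
            label="c3", count=272,
            centers=((0.60, 0.40), (0.30, 0.20)), spread=0.30,
        ),
    )
    return make_imbalanced(
        GeneratorSpec(class_specs=specs, n_features=2, noise_fraction=0.05, seed=seed)
    )
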