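"""Dataset container, CSV I/O, normalization and class bookkeeping.

Every stage of the resampling pipelines consumes and produces a
:class:`LabeledDataset`: a numeric feature matrix with one categorical
label per row. Features are expected to be min-max normalized to [0, 1]
before density-based noise removal, so that a neighborhood radius such as
eps = 0.1 means the same thing across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabeledDataset",
    "ClassPartition",
    "PreprocessConfig",
    "load_csv_dataset",
    "write_csv_dataset",
    "minmax_normalize",
    "partition_by_class",
]


@dataclass(frozen=True)
class LabeledDataset:
    """A numeric feature matrix with one categorical label per row.

    Parameters
    ----------
    features : ndarray of shape (n_samples, n_features)
        Finite numeric feature values.
    labels : ndarray of shape (n_samples,)
        Class label per row. Stored as strings for determinism across
        CSV round trips.
    feature_names : list of str, optional
        Column names; defaults to ``f0, f1, ...`` when written to CSV.
    label_name : str, optional
        Name of the label column; defaults to ``label``.
    """

    features: np.ndarray
    labels: np.ndarray
    feature_names: tuple[str, ...] | None = None
    label_name: str | None = None

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=float)
        labels = np.asarray(self.labels)
        if features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        if labels.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        if features.shape[0] != labels.shape[0]:
            raise ValueError(
                f"row mismatch: {features.shape[0]} feature rows vs "
                f"{labels.shape[0]} labels"
            )
        if not np.isfinite(features).all():
            raise ValueError("features contain non-finite values (NaN/inf)")
        if self.feature_names is not None and len(self.feature_names) != features.shape[1]:
            raise ValueError("feature_names length does not match feature count")
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "labels", labels.astype(str))
        if self.feature_names is not None:
            object.__setattr__(self, "feature_names", tuple(self.feature_names))

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[str, int]:
        values, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(values.tolist(), counts.tolist()))

    def subset(self, indices) -> "LabeledDataset":
        idx = np.asarray(indices, dtype=int)
        return replace(self, features=self.features[idx], labels=self.labels[idx])

    def class_matrix(self, label: str) -> np.ndarray:
        """Feature rows belonging to one class, in row order."""
        return self.features[self.labels == str(label)]

    def to_frame(self) -> pd.DataFrame:
        names = self.feature_names or tuple(f"f{i}" for i in range(self.n_features))
        frame = pd.DataFrame(self.features, columns=list(names))
        frame[self.label_name or "label"] = self.labels
        return frame


@dataclass(frozen=True)
class ClassPartition:
    """Row indices and counts for every class of a dataset.

    ``majority`` attains the maximal count; ties go to the class earliest
    in sorted label order so the choice is deterministic.
    """

    classes: tuple[str, ...]
    counts: dict[str, int]
    indices: dict[str, np.ndarray]
    majority: str

    @property
    def majority_count(self) -> int:
        return self.counts[self.majority]

    def minority_classes(self) -> tuple[str, ...]:
        return tuple(c for c in self.classes if c != self.majority)


@dataclass(frozen=True)
class PreprocessConfig:
    """CSV loading options.

    ``label_column`` is a column name or integer position; -1 (default)
    means the last column. ``normalization`` is applied by callers via
    :func:`minmax_normalize`; ``"none"`` leaves features untouched.
    """

    normalization: str = "minmax"
    label_column: str | int = -1
    delimiter: str = ","

    def __post_init__(self) -> None:
        if self.normalization not in ("minmax", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")


def load_csv_dataset(path, config: PreprocessConfig = PreprocessConfig()) -> LabeledDataset:
    """Load a header-row CSV into a :class:`LabeledDataset`.

    Every non-label column must parse as numeric with no missing values;
    a failing cell is reported with its row and column. The label column
    is taken verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"dataset file not found: {path}")
    frame = pd.read_csv(path, sep=config.delimiter, dtype=str, skipinitialspace=True)
    if frame.shape[0] == 0:
        raise ValueError(f"dataset file {path} contains a header but no data rows")

    if isinstance(config.label_column, int):
        try:
            label_col = frame.columns[config.label_column]
        except IndexError:
            raise ValueError(
                f"label column index {config.label_column} out of range "
                f"for {frame.shape[1]} columns"
            ) from None
    else:
        if config.label_column not in frame.columns:
            raise ValueError(f"label column {config.label_column!r} not found in {path}")
        label_col = config.label_column

    labels = frame[label_col].to_numpy(dtype=str)
    feature_frame = frame.drop(columns=[label_col])
    parsed = {}
    for col in feature_frame.columns:
        raw = feature_frame[col].to_numpy()
        try:
            # numpy's parser round-trips the shortest-repr floats we write
            values = raw.astype(float)
            bad_mask = np.isnan(values)
        except (TypeError, ValueError):
            coerced = pd.to_numeric(feature_frame[col], errors="coerce")
            bad_mask = coerced.isna().to_numpy()
            values = coerced.to_numpy(dtype=float)
        if bad_mask.any():
            row = int(np.flatnonzero(bad_mask)[0])
            raise ValueError(
                f"non-numeric or missing feature value at data row {row}, "
                f"column {col!r}: {feature_frame[col].iloc[row]!r}"
            )
        parsed[col] = values
    features = np.column_stack([parsed[c] for c in feature_frame.columns])
    return LabeledDataset(
        features=features,
        labels=labels,
        feature_names=tuple(feature_frame.columns),
        label_name=str(label_col),
    )


def write_csv_dataset(dataset: LabeledDataset, path, delimiter: str = ",") -> None:
    """Write the same CSV dialect :func:`load_csv_dataset` reads (round-trip safe)."""
    frame = dataset.to_frame()
    # default float formatting is shortest-round-trip, so loading is exact
    frame.to_csv(path, sep=delimiter, index=False)


def minmax_normalize(
    dataset: LabeledDataset, reference: LabeledDataset | None = None
) -> LabeledDataset:
    """Map each feature to [0, 1] by (x - min) / (max - min).

    Statistics come from ``reference`` when given (the training portion,
    to keep test folds untouched by their own statistics) and from the
    dataset itself otherwise. Constant features map to 0. Values outside
    the reference range map outside [0, 1]; that is intentional for test
    folds.
    """
    ref = reference if reference is not None else dataset
    if ref.n_features != dataset.n_features:
        raise ValueError(
            f"reference has {ref.n_features} features, dataset has {dataset.n_features}"
        )
    lo = ref.features.min(axis=0)
    hi = ref.features.max(axis=0)
    span = hi - lo
    scaled = np.zeros_like(dataset.features)
    nonconst = span > 0
    scaled[:, nonconst] = (dataset.features[:, nonconst] - lo[nonconst]) / span[nonconst]
    return replace(dataset, features=scaled)


def partition_by_class(dataset: LabeledDataset) -> ClassPartition:
    """Index rows by class; majority ties break to the earliest sorted label."""
    if dataset.n_samples == 0:
        raise ValueError("cannot partition an empty dataset")
    classes = np.unique(dataset.labels)  # sorted
    counts = {}
    indices = {}
    for cls in classes:
        idx = np.flatnonzero(dataset.labels == cls)
        counts[str(cls)] = int(idx.size)
        indices[str(cls)] = idx
    majority = max(sorted(counts), key=lambda c: counts[c])  # max is stable: first maximal
    return ClassPartition(
        classes=tuple(str(c) for c in classes),
        counts=counts,
        indices=indices,
        majority=majority,
    )
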