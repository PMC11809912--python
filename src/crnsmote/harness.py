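"""Cross-validation harness with fold-wise resampling.

Resampling must never see the test fold: within each fold the training
portion is min-max normalized (statistics from the training rows only),
resampled, and fed to a classifier at library defaults; the untouched
test fold is normalized with the training statistics and scored with the
imbalanced-classification metrics. Per-fold reports and their arithmetic
mean are returned for every (dataset, resampler, classifier, K_SMOTE)
cell of the evaluation grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import LabeledDataset, minmax_normalize, partition_by_class
from .dbscan import DbscanParams
from .metrics import MetricReport, binary_metrics, confusion, multiclass_metrics
from .resample import CrnConfig, crn_smote, rn_smote, smote_enn, smote_tomek

__all__ = [
    "CvConfig",
    "EvalRow",
    "RESAMPLERS",
    "CLASSIFIERS",
    "stratified_folds",
    "run_cell",
    "grid_report",
    "compare_methods",
    "rows_to_frame",
]

_METRIC_NAMES = ("kappa", "mcc", "f1", "precision", "recall")


def _resample_none(dataset, k_smote, seed):
    return dataset


def _resample_rn(dataset, k_smote, seed):
    return rn_smote(dataset, k_smote=k_smote, dbscan_params="auto", seed=seed).data


def _resample_crn(n_cluster):
    def inner(dataset, k_smote, seed):
        cfg = CrnConfig(n_cluster=n_cluster, k_smote=k_smote, seed=seed)
        return crn_smote(dataset, cfg).data

    return inner


def _resample_smote_tomek(dataset, k_smote, seed):
    return smote_tomek(dataset, k_smote=k_smote, seed=seed).data


def _resample_smote_enn(dataset, k_smote, seed):
    return smote_enn(dataset, k_smote=k_smote, seed=seed).data


RESAMPLERS = {
    "none": _resample_none,
    "rn_smote": _resample_rn,
    "crn1": _resample_crn(1),
    "crn2": _resample_crn(2),
    "smote_tomek": _resample_smote_tomek,
    "smote_enn": _resample_smote_enn,
}


def _make_classifier(name: str, seed: int):
    # library defaults per the evaluation protocol; only the RNG is pinned
    if name == "svm":
        return SVC(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    raise ValueError(f"unknown classifier {name!r}")


CLASSIFIERS = ("svm", "random_forest", "adaboost")


@dataclass(frozen=True)
class CvConfig:
    """Grid and fold settings for the evaluation protocol."""

    n_folds: int = 10
    seed: int = 0
    resamplers: tuple[str, ...] = ("none", "rn_smote", "crn1", "crn2")
    classifiers: tuple[str, ...] = ("svm", "random_forest", "adaboost")
    k_smote_grid: tuple[int, ...] = (4, 5, 6)

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for r in self.resamplers:
            if r not in RESAMPLERS:
                raise ValueError(f"unknown resampler {r!r}")
        for c in self.classifiers:
            if c not in CLASSIFIERS:
                raise ValueError(f"unknown classifier {c!r}")


@dataclass(frozen=True)
class EvalRow:
    """One grid cell: mean and per-fold metrics (or a recorded failure)."""

    dataset_id: str
    resampler: str
    classifier: str
    k_smote: int
    mean: MetricReport | None
    per_fold: tuple[MetricReport, ...]
    failed: bool = False
    error: str | None = None


def stratified_folds(dataset: LabeledDataset, n_folds: int, seed: int) -> list[np.ndarray]:
    """Disjoint, covering test-fold index lists with per-class counts within 1."""
    part = partition_by_class(dataset)
    small = [c for c in part.classes if part.counts[c] < n_folds]
    if small:
        raise ValueError(
            f"classes {small} have fewer than n_folds={n_folds} samples; "
            "stratification impossible"
        )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [test for _, test in splitter.split(dataset.features, dataset.labels)]


def _mean_report(reports: list[MetricReport]) -> MetricReport:
    return MetricReport(
        **{
            name: float(np.mean([getattr(r, name) for r in reports]))
            for name in _METRIC_NAMES
        }
    )


def _score(actual, predicted, class_order, minority: str) -> MetricReport:
    cm = confusion(actual, predicted, class_order)
    if len(class_order) == 2:
        return binary_metrics(cm, positive=minority)
    return multiclass_metrics(cm)


def run_cell(
    dataset: LabeledDataset,
    resampler: str,
    classifier: str,
    k_smote: int,
    cv: CvConfig,
    dataset_id: str = "dataset",
) -> EvalRow:
    """Score one (resampler, classifier, K_SMOTE) cell by fold-wise resampling.

    Only the training portion of each fold is resampled (seed =
    ``cv.seed + fold``); the test fold is predicted untouched. The
    minority class of the full dataset is the positive class for binary
    metrics; 3+ classes use macro averaging.
    """
    part = partition_by_class(dataset)
    minority = min(sorted(part.counts), key=lambda c: part.counts[c])
    class_order = part.classes
    resample = RESAMPLERS[resampler]
    all_rows = np.arange(dataset.n_samples)

    reports: list[MetricReport] = []
    try:
        folds = stratified_folds(dataset, cv.n_folds, cv.seed)
        for fold_id, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(all_rows, test_idx)
            train = dataset.subset(train_idx)
            test = dataset.subset(test_idx)
            test = minmax_normalize(test, reference=train)
            train = minmax_normalize(train)
            balanced = resample(train, k_smote, cv.seed + fold_id)
            model = _make_classifier(classifier, cv.seed)
            model.fit(balanced.features, balanced.labels)
            predicted = model.predict(test.features)
            reports.append(_score(test.labels, predicted, class_order, minority))
    except Exception as exc:  # a failed fold fails the whole cell, loudly
        return EvalRow(
            dataset_id=dataset_id, resampler=resampler, classifier=classifier,
            k_smote=k_smote, mean=None, per_fold=tuple(reports),
            failed=True, error=f"{type(exc).__name__}: {exc}",
        )
    return EvalRow(
        dataset_id=dataset_id, resampler=resampler, classifier=classifier,
        k_smote=k_smote, mean=_mean_report(reports), per_fold=tuple(reports),
    )


def grid_report(datasets: dict[str, LabeledDataset], cv: CvConfig) -> list[EvalRow]:
    """One row per dataset x resampler x classifier x K_SMOTE.

    The no-resampling baseline does not depend on K_SMOTE, so its cell is
    computed once per classifier and repeated across the grid.
    """
    rows: list[EvalRow] = []
    for name, dataset in datasets.items():
        for clf in cv.classifiers:
            cached_none: EvalRow | None = None
            for res in cv.resamplers:
                for k in cv.k_smote_grid:
                    if res == "none":
                        if cached_none is None:
                            cached_none = run_cell(dataset, res, clf, k, cv, dataset_id=name)
                        row = EvalRow(
                            dataset_id=name, resampler=res, classifier=clf, k_smote=k,
                            mean=cached_none.mean, per_fold=cached_none.per_fold,
                            failed=cached_none.failed, error=cached_none.error,
                        )
                    else:
                        row = run_cell(dataset, res, clf, k, cv, dataset_id=name)
                    rows.append(row)
    return rows


def compare_methods(dataset: LabeledDataset, cv: CvConfig, dataset_id: str = "dataset") -> pd.DataFrame:
    """Head-to-head table: the four cleanup methods, random forest, K_SMOTE = 5.

    Rows are ranked by kappa, the headline chance-corrected score.
    """
    methods = ("crn1", "smote_enn", "smote_tomek", "rn_smote")
    rows = [run_cell(dataset, m, "random_forest", 5, cv, dataset_id=dataset_id) for m in methods]
    frame = rows_to_frame(rows)
    return frame.sort_values("kappa", ascending=False).reset_index(drop=True)


def rows_to_frame(rows: list[EvalRow]) -> pd.DataFrame:
    """Flatten mean metrics into a tidy table (one row per grid cell)."""
    records = []
    for row in rows:
        rec = {
            "dataset": row.dataset_id,
            "resampler": row.resampler,
            "classifier": row.classifier,
            "k_smote": row.k_smote,
            "failed": row.failed,
        }
        if row.mean is not None:
            rec.update(row.mean.to_dict())
        else:
            rec.update({name: float("nan") for name in _METRIC_NAMES})
            rec["error"] = row.error
        records.append(rec)
    return pd.DataFrame.from_records(records)
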