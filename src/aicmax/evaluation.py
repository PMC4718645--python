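"""Cross-validated evaluation of reduced fingerprint representations.

The protocol mirrors a leakage-free virtual-screening validation: within
each of k folds, bit selection runs only on the pooled training compounds of
all targets (actives, inactives and putative inactives merged), then a
per-target classifier is trained on that target's training fold restricted
to the selected bits and scored on the held-out fold.  Classification
quality is summarized by the Matthews correlation coefficient (MCC), the
standard choice for the heavily imbalanced 9:1 active/putative-inactive
datasets of this domain; representation quality can alternatively be scored
as the normalized mutual information of the selected bits with the held-out
labels.

Folds are stratified by default so that every training fold of a 10%-active
dataset retains both classes; plain random partitioning is available via
``stratified=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .data import ActivitySet, TargetCollection
from .info import normalized_mi, shannon_entropy
from .selection import SelectionConfig, aic_max_select

__all__ = [
    "ConfusionCounts",
    "FoldAssignment",
    "CVResult",
    "matthews_cc",
    "confusion_from_predictions",
    "kfold_partition",
    "cv_folds",
    "evaluate_reduced_representation",
    "information_score_cv",
    "default_classifier_factory",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix tallies: true/false positives and negatives."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def matthews_cc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient in [-1, 1].

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); +1 is perfect
    prediction, 0 random, -1 inverse.  When any marginal is empty the
    denominator vanishes and the coefficient is defined as 0, the usual
    convention for a constant predictor.
    """
    if counts.total == 0:
        raise ValueError("confusion counts are all zero")
    tp, tn, fp, fn = (float(x) for x in (counts.tp, counts.tn, counts.fp, counts.fn))
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0.0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(np.int64)
    y_pred = np.asarray(y_pred).astype(np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


@dataclass(frozen=True)
class FoldAssignment:
    """Fold index per compound for one target's k-fold partition."""

    fold_index: np.ndarray
    k: int
    seed: int
    stratified: bool


def kfold_partition(
    activity: ActivitySet, k: int, seed: int, stratified: bool = True
) -> FoldAssignment:
    """Random k-fold partition of one target's compounds, reproducible by seed.

    Folds are disjoint, cover every compound, and differ in size by at most
    one (per class when stratified).
    """
    n = activity.n_compounds
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n}-compound dataset")
    if stratified:
        counts = np.bincount(activity.labels.astype(np.int64), minlength=2)
        if counts.min() < k:
            raise ValueError(
                f"target {activity.target_id!r}: smallest class has "
                f"{counts.min()} members, cannot stratify into {k} folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    fold_index = np.empty(n, dtype=np.int64)
    dummy = np.zeros((n, 1))
    for f, (_, test_idx) in enumerate(splitter.split(dummy, activity.labels)):
        fold_index[test_idx] = f
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed, stratified=stratified)


def _child_seed(seed: int, *key: int) -> int:
    return int(np.random.default_rng([seed, *key]).integers(2**31))


def default_classifier_factory(seed: int):
    """Random-forest classifier, the field's default for activity prediction."""
    return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)


def cv_folds(
    collection: TargetCollection, k: int, seed: int, stratified: bool = True
) -> Iterator[tuple[int, list[ActivitySet], list[ActivitySet]]]:
    """Yield (fold, training sets, test sets) over all targets.

    Each target is partitioned independently (compound sets differ between
    targets); fold f's training data is every target's out-of-fold subset.
    Training folds with constant labels are rejected because selection and
    normalized scoring are undefined on them.
    """
    assignments = [
        kfold_partition(a, k, seed=_child_seed(seed, i), stratified=stratified)
        for i, a in enumerate(collection.activity_sets)
    ]
    for f in range(k):
        train_sets, test_sets = [], []
        for a, fa in zip(collection.activity_sets, assignments):
            train_mask = fa.fold_index != f
            train = a.subset(train_mask)
            if shannon_entropy(train.labels) == 0.0:
                raise ValueError(
                    f"degenerate training fold {f} for target {a.target_id!r}: "
                    "activity labels are constant"
                )
            train_sets.append(train)
            test_sets.append(a.subset(~train_mask))
        yield f, train_sets, test_sets


@dataclass
class CVResult:
    """Per-fold score table with per-target and grand means."""

    per_fold: pd.DataFrame
    metric: str

    @property
    def per_target_mean(self) -> pd.Series:
        return self.per_fold.groupby("target_id", sort=False)[self.metric].mean()

    @property
    def grand_mean(self) -> float:
        return float(self.per_target_mean.mean())


def _run_cv(
    collection: TargetCollection,
    config: SelectionConfig,
    k: int,
    seed: int,
    stratified: bool,
    classifier_factory: Callable[[int], object] | None,
    with_classifier: bool,
) -> pd.DataFrame:
    if classifier_factory is None:
        classifier_factory = default_classifier_factory
    rows = []
    for f, train_sets, test_sets in cv_folds(collection, k, seed, stratified):
        selected = aic_max_select(
            TargetCollection(train_sets), config
        ).selected
        for i, (train, test) in enumerate(zip(train_sets, test_sets)):
            row = {
                "target_id": train.target_id,
                "fold": f,
                "n_bits": len(selected),
                "norm_mi": normalized_mi(test, selected),
            }
            if with_classifier:
                clf = classifier_factory(_child_seed(seed, f, i))
                clf.fit(train.matrix.columns(selected), train.labels)
                pred = np.asarray(clf.predict(test.matrix.columns(selected)))
                if not np.isin(pred, (0, 1)).all():
                    raise ValueError(
                        "classifier contract violation: predictions must be binary"
                    )
                row["mcc"] = matthews_cc(confusion_from_predictions(test.labels, pred))
            rows.append(row)
    return pd.DataFrame(rows)


def evaluate_reduced_representation(
    collection: TargetCollection,
    config: SelectionConfig,
    k: int = 10,
    seed: int = 0,
    classifier_factory: Callable[[int], object] | None = None,
    stratified: bool = True,
) -> CVResult:
    """k-fold CV of in-fold bit selection followed by per-target classification.

    The classifier factory takes a seed and returns any object with sklearn's
    fit/predict contract on binary matrices; the default is a 100-tree random
    forest.  Scores are MCC on held-out folds (a ``norm_mi`` column is
    included alongside for the same folds and selections).
    """
    per_fold = _run_cv(
        collection, config, k, seed, stratified, classifier_factory, True
    )
    return CVResult(per_fold=per_fold, metric="mcc")


def information_score_cv(
    collection: TargetCollection,
    config: SelectionConfig,
    k: int = 10,
    seed: int = 0,
    stratified: bool = True,
) -> CVResult:
    """As :func:`evaluate_reduced_representation` but scoring held-out
    normalized MI of the selected bits instead of training a classifier."""
    per_fold = _run_cv(collection, config, k, seed, stratified, None, False)
    return CVResult(per_fold=per_fold, metric="norm_mi")
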