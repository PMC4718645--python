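"""Empirical information-theoretic primitives.

All quantities use plug-in (maximum-likelihood) probability estimates —
observed counts over totals, no pseudocounts — and base-2 logarithms, so
entropies and mutual informations are in bits.  A set of binary features is
treated jointly as a single discrete variable over its observed bit
patterns; patterns that never occur have zero empirical probability and are
simply not enumerated, which keeps the computation sparse even when the
pattern space 2^N is astronomically large.

The headline score is the average information content (AIC) of a feature
set X against K targets:

    AIC_Y(X) = (1/K) * sum_i MI(X; Y_i) / SE(Y_i)

i.e. the mutual information between the joint bit pattern and each target's
activity labels, normalized by the entropy of those labels and averaged over
targets.  Each per-target factor is the fraction of that target's activity
information captured by X, so 0 <= AIC <= 1, and AIC = 1 means X fully
determines activity for every target.  Every factor is estimated on that
target's own compound set, which is what lets the score combine targets
whose ligand sets are disjoint.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import stats

from .data import ActivitySet, TargetCollection

__all__ = [
    "shannon_entropy",
    "joint_mutual_information",
    "normalized_mi",
    "average_information_content",
]


def shannon_entropy(labels) -> float:
    """Shannon entropy, in bits, of a binary label vector.

    Plug-in estimate -sum_y p(y) log2 p(y) with 0*log 0 := 0.  For binary
    labels the result lies in [0, 1]; it is 0 iff the labels are constant.
    """
    arr = np.asarray(labels)
    if arr.size == 0:
        raise ValueError("no observations")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("labels must be binary")
    counts = np.bincount(arr.astype(np.int64).ravel(), minlength=2)
    return float(stats.entropy(counts, base=2))


def _joint_codes(columns: np.ndarray) -> np.ndarray:
    """One integer per row encoding the joint bit pattern of the columns.

    Codes are compact (0..k-1 over the k observed patterns) so downstream
    contingency tables stay small regardless of how many bits are combined.
    """
    n, m = columns.shape
    if m <= 62:
        codes = columns[:, 0].astype(np.int64)
        for j in range(1, m):
            codes = (codes << 1) | columns[:, j]
    else:  # avoid int64 overflow; unique-rows is O(n m log n) but rare
        _, codes = np.unique(columns, axis=0, return_inverse=True)
    _, compact = np.unique(codes, return_inverse=True)
    return compact


def _mi_bits(codes: np.ndarray, labels: np.ndarray) -> float:
    """Plug-in MI in bits between compact integer codes and binary labels.

    Tiny negative values from floating-point cancellation are clamped to 0.
    """
    n = codes.size
    k = int(codes.max()) + 1
    joint = np.bincount(codes * 2 + labels, minlength=2 * k).reshape(k, 2)
    joint = joint.astype(np.float64)
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(
        (joint[nz] / n * (np.log2(joint[nz] * n) - np.log2(np.outer(px, py)[nz]))).sum()
    )
    return max(mi, 0.0)


def joint_mutual_information(
    activity: ActivitySet, feature_ids: Sequence[str]
) -> float:
    """MI, in bits, between the joint pattern of the features and the labels.

    The selected columns are treated as one discrete variable over their
    observed bit patterns.  Satisfies 0 <= MI <= min(SE(pattern), SE(labels)).
    """
    feature_ids = list(feature_ids)
    if not feature_ids:
        raise ValueError("empty feature set")
    codes = _joint_codes(activity.matrix.columns(feature_ids))
    return _mi_bits(codes, activity.labels.astype(np.int64))


def normalized_mi(activity: ActivitySet, feature_ids: Sequence[str]) -> float:
    """Fraction in [0, 1] of the labels' entropy explained by the features.

    MI(X; Y) / SE(Y).  Raises for constant labels, whose entropy is zero:
    such a target carries no activity signal to normalize against, and
    silently dropping it would bias the multi-target average.
    """
    se = shannon_entropy(activity.labels)
    if se == 0.0:
        raise ValueError(
            "degenerate target: entropy of activity labels is zero "
            f"(target {activity.target_id!r})"
        )
    return min(joint_mutual_information(activity, feature_ids) / se, 1.0)


def average_information_content(
    collection: TargetCollection, feature_ids: Sequence[str]
) -> float:
    """Average information content of a feature set over all targets.

    Mean of per-target normalized MI; each factor uses only that target's
    own compound set (the marginal P(x) is per-target).  In [0, 1].
    """
    return float(
        np.mean([normalized_mi(a, feature_ids) for a in collection.activity_sets])
    )
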