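"""Entropy, joint MI and average information content on known cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import mutual_info_score

from aicmax import (
    ActivitySet,
    BitMatrix,
    TargetCollection,
    average_information_content,
    joint_mutual_information,
    normalized_mi,
    shannon_entropy,
)

from conftest import brute_force_joint_mi, random_collection

# closed forms for the 8-compound AND example: labels are 2 actives / 6
# inactives, and X1 splits them into a pure half and a 50:50 half
SE_Y = -(1 / 4) * np.log2(1 / 4) - (3 / 4) * np.log2(3 / 4)
MI_X1_Y = SE_Y - 0.5  # H(Y) - H(Y|X1), with H(Y|X1) = 0.5 * 1 bit


@pytest.mark.parametrize(
    "labels, expected",
    [
        ([0, 0, 0, 0, 1, 1, 1, 1], 1.0),
        ([1, 1, 1, 1], 0.0),
        ([0, 0, 0, 0, 0, 0, 1, 1], SE_Y),
    ],
)
def test_entropy_closed_forms(labels, expected):
    assert shannon_entropy(labels) == pytest.approx(expected, abs=1e-12)


def test_entropy_rejects_bad_input():
    with pytest.raises(ValueError, match="no observations"):
        shannon_entropy([])
    with pytest.raises(ValueError, match="binary"):
        shannon_entropy([0, 2, 1])


def test_joint_mi_and_example(table2):
    activity = table2.activity_sets[0]
    assert joint_mutual_information(activity, ["X1"]) == pytest.approx(MI_X1_Y, abs=1e-12)
    # X3 is independent of Y by construction
    assert joint_mutual_information(activity, ["X3"]) == pytest.approx(0.0, abs=1e-12)
    # the full pair determines Y, so MI saturates at SE(Y)
    assert joint_mutual_information(activity, ["X1", "X2"]) == pytest.approx(SE_Y, abs=1e-12)


def test_mi_of_a_label_copy_equals_label_entropy():
    rng = np.random.default_rng(7)
    labels = rng.integers(0, 2, size=40, dtype=np.uint8)
    values = np.column_stack([labels, rng.integers(0, 2, size=40, dtype=np.uint8)])
    activity = ActivitySet(
        BitMatrix(values, ["copy", "other"], [f"c{i}" for i in range(40)]), labels, "T"
    )
    assert joint_mutual_information(activity, ["copy"]) == pytest.approx(
        shannon_entropy(labels), abs=1e-12
    )
    assert normalized_mi(activity, ["copy"]) == pytest.approx(1.0, abs=1e-12)


def test_joint_mi_input_validation(table2):
    activity = table2.activity_sets[0]
    with pytest.raises(ValueError, match="empty feature set"):
        joint_mutual_information(activity, [])
    with pytest.raises(ValueError, match="unknown feature_id"):
        joint_mutual_information(activity, ["X9"])


def test_normalized_mi_matches_printed_value(table2):
    activity = table2.activity_sets[0]
    assert round(normalized_mi(activity, ["X1"]), 2) == 0.38
    assert normalized_mi(activity, ["X1"]) == pytest.approx(MI_X1_Y / SE_Y, abs=1e-12)


def test_normalized_mi_degenerate_labels_error():
    matrix = BitMatrix(np.eye(3, dtype=np.uint8), ["a", "b", "c"], ["1", "2", "3"])
    activity = ActivitySet(matrix, np.ones(3, dtype=np.uint8), "flat")
    with pytest.raises(ValueError, match="degenerate target.*flat"):
        normalized_mi(activity, ["a"])


def test_aic_extremes_on_independent_single_bit_targets(table1):
    # each bit fully determines its own target and none of the others
    for i, activity in enumerate(table1.activity_sets):
        own = TargetCollection([activity])
        assert average_information_content(own, [f"X{i + 1}"]) == pytest.approx(1.0, abs=1e-12)
        for j in range(3):
            if j != i:
                assert average_information_content(own, [f"X{j + 1}"]) == pytest.approx(
                    0.0, abs=1e-12
                )
    # two bits cover two of three targets
    assert average_information_content(table1, ["X1", "X2"]) == pytest.approx(
        2 / 3, abs=1e-12
    )


def test_aic_unchanged_by_anticorrelated_bit(table2):
    a = average_information_content(table2, ["X1"])
    b = average_information_content(table2, ["X1", "X4"])
    assert round(b, 2) == 0.38
    assert abs(a - b) < 1e-12


@pytest.mark.parametrize("seed", range(6))
def test_joint_mi_agrees_with_dense_enumeration(seed):
    rng = np.random.default_rng(seed)
    collection = random_collection(rng, n_compounds=25, n_features=8)
    activity = collection.activity_sets[0]
    universe = activity.matrix.feature_ids
    for size in (1, 2, 4, 8):
        ids = list(rng.choice(universe, size=size, replace=False))
        assert joint_mutual_information(activity, ids) == pytest.approx(
            brute_force_joint_mi(activity, ids), abs=1e-12
        )


@pytest.mark.parametrize("seed", range(4))
def test_single_feature_mi_agrees_with_sklearn(seed):
    rng = np.random.default_rng(seed)
    collection = random_collection(rng, n_compounds=60, n_features=4)
    activity = collection.activity_sets[0]
    for fid in activity.matrix.feature_ids:
        ours = joint_mutual_information(activity, [fid])
        ref = mutual_info_score(activity.labels, activity.matrix.columns([fid])[:, 0])
        assert ours == pytest.approx(ref / np.log(2), abs=1e-10)


# --- property-based invariants --------------------------------------------

binary_matrix = st.integers(2, 30).flatmap(
    lambda n: st.tuples(
        st.lists(
            st.lists(st.integers(0, 1), min_size=5, max_size=5),
            min_size=n,
            max_size=n,
        ),
        st.lists(st.integers(0, 1), min_size=n, max_size=n),
    )
)


def _activity(rows, labels):
    values = np.array(rows, dtype=np.uint8)
    matrix = BitMatrix(
        values, [f"f{j}" for j in range(values.shape[1])],
        [f"c{i}" for i in range(values.shape[0])],
    )
    return ActivitySet(matrix, np.array(labels, dtype=np.uint8), "T")


@settings(max_examples=80, deadline=None, derandomize=True)
@given(binary_matrix)
def test_mi_bounds_and_symmetry(data):
    rows, labels = data
    activity = _activity(rows, labels)
    ids = activity.matrix.feature_ids[:3]
    mi = joint_mutual_information(activity, ids)
    joint_entropy = shannon_entropy_of_patterns(activity, ids)
    assert mi >= 0.0
    assert mi <= min(joint_entropy, shannon_entropy(labels)) + 1e-9
    assert mi == pytest.approx(
        joint_mutual_information(activity, list(reversed(ids))), abs=1e-12
    )


def shannon_entropy_of_patterns(activity, ids):
    cols = activity.matrix.columns(ids)
    _, counts = np.unique(cols, axis=0, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


@settings(max_examples=80, deadline=None, derandomize=True)
@given(binary_matrix)
def test_mi_monotone_under_extension_and_redundancy_invariant(data):
    rows, labels = data
    activity = _activity(rows, labels)
    universe = activity.matrix.feature_ids
    small, large = universe[:2], universe[:4]
    assert joint_mutual_information(activity, small) <= (
        joint_mutual_information(activity, large) + 1e-9
    )
    # appending a duplicated column changes nothing
    values = activity.matrix.values
    dup = np.column_stack([values, values[:, 0], 1 - values[:, 0]])
    extended = ActivitySet(
        BitMatrix(dup, universe + ["dup", "neg"], activity.matrix.compound_ids),
        activity.labels,
        "T",
    )
    base = joint_mutual_information(extended, small)
    assert joint_mutual_information(extended, small + ["dup"]) == pytest.approx(base, abs=1e-12)
    assert joint_mutual_information(extended, small + ["neg"]) == pytest.approx(base, abs=1e-12)
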