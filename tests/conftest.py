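import numpy as np
import pytest

from aicmax import ActivitySet, BitMatrix, TargetCollection, table1_fixture, table2_fixture


@pytest.fixture
def table1():
    return table1_fixture()


@pytest.fixture
def table2():
    return table2_fixture()


def random_collection(
    rng: np.random.Generator,
    n_targets: int = 1,
    n_compounds: int = 30,
    n_features: int = 6,
) -> TargetCollection:
    """Small random binary collection with non-degenerate labels."""
    universe = [f"fp:{j}" for j in range(n_features)]
    sets = []
    for t in range(n_targets):
        values = rng.integers(0, 2, size=(n_compounds, n_features), dtype=np.uint8)
        labels = np.zeros(n_compounds, dtype=np.uint8)
        while labels.min() == labels.max():
            labels = rng.integers(0, 2, size=n_compounds, dtype=np.uint8)
        matrix = BitMatrix(values, list(universe), [f"T{t}c{i}" for i in range(n_compounds)])
        sets.append(ActivitySet(matrix, labels, f"T{t}"))
    return TargetCollection(sets)


def brute_force_joint_mi(activity: ActivitySet, feature_ids) -> float:
    """Dense plug-in MI enumerating all 2^N patterns explicitly.

    Independent of the package's sparse pattern-coding path; only usable
    for small feature sets.
    """
    cols = activity.matrix.columns(feature_ids)
    y = activity.labels
    n, m = cols.shape
    total = 0.0
    for pattern in range(2 ** m):
        bits = [(pattern >> (m - 1 - j)) & 1 for j in range(m)]
        in_pattern = np.all(cols == np.array(bits, dtype=np.uint8), axis=1)
        px = in_pattern.mean()
        if px == 0:
            continue
        for label in (0, 1):
            pxy = float((in_pattern & (y == label)).mean())
            py = float((y == label).mean())
            if pxy > 0:
                total += pxy * np.log2(pxy / (px * py))
    return max(total, 0.0)
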