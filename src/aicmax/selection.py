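"""Greedy maximization of average information content (AIC-Max).

The exact subset-selection problem — find the N-element feature set with
maximal AIC — is combinatorial (C(1434, 100) for a realistic hybrid
fingerprint), so the workhorse is a greedy forward search: at each step add
the candidate bit whose union with the already-selected bits yields the
highest AIC.  Because the score is evaluated on the *joint* pattern, a bit
that is a duplicate (or negation) of an already-selected bit contributes no
gain and is passed over whenever any alternative offers strictly positive
gain.

Conditioning on all selected bits makes each step cost grow with the
selection; the optional subsample heuristic instead conditions each step on
a random n-bit subset of the selection (default n = 10).  One subset is
drawn per iteration and shared by all candidates of that iteration, so
candidates are compared against the same context.  The reported trace is
always the exact AIC of the full selected prefix, independent of the
subsample, so information curves are comparable across configurations.

:func:`exhaustive_best_subset` enumerates every subset of a given size and
serves as a ground-truth oracle on small instances.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import TargetCollection
from .info import _joint_codes, _mi_bits, shannon_entropy

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "aic_max_select",
    "exhaustive_best_subset",
    "information_curve",
    "selection_result_from_features",
]

logger = logging.getLogger(__name__)

# scores closer than this are treated as tied and broken to the lower
# feature-universe index, so float jitter cannot flip a selection
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of one greedy selection run.

    Parameters
    ----------
    n_select
        Number of bits to pick (the length N of the reduced fingerprint).
    subsample_size
        Condition each step's candidate scores on a random subset of at most
        this many already-selected bits; ``None`` conditions on all of them
        (exact greedy).  Default 10.
    seed
        Seed for the subsample draws; ignored in exact mode but recorded.
    """

    n_select: int
    subsample_size: int | None = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.subsample_size is not None and self.subsample_size < 1:
            raise ValueError("subsample_size must be >= 1 or None")


@dataclass
class SelectionResult:
    """Ordered selection with its exact per-step information trace."""

    selected: list[str]
    aic_trace: list[float]
    per_target_trace: list[dict[str, float]]
    config: SelectionConfig

    def __post_init__(self) -> None:
        if not (len(self.selected) == len(self.aic_trace) == len(self.per_target_trace)):
            raise ValueError("trace lengths must match the number of selected features")


def _prepare_targets(collection: TargetCollection):
    """Per-target (values, labels, entropy) with a hard degenerate-target check."""
    prepared = []
    for a in collection.activity_sets:
        se = shannon_entropy(a.labels)
        if se == 0.0:
            raise ValueError(
                "degenerate target: entropy of activity labels is zero "
                f"(target {a.target_id!r})"
            )
        prepared.append((a.matrix.values, a.labels.astype(np.int64), se, a.target_id))
    return prepared


def _aic_indices(prepared, indices: Sequence[int]) -> tuple[float, dict[str, float]]:
    per_target = {}
    for values, labels, se, tid in prepared:
        codes = _joint_codes(values[:, list(indices)])
        per_target[tid] = min(_mi_bits(codes, labels) / se, 1.0)
    return float(np.mean(list(per_target.values()))), per_target


def aic_max_select(
    collection: TargetCollection, config: SelectionConfig
) -> SelectionResult:
    """Greedy forward selection of the ``config.n_select`` most informative bits.

    Deterministic given ``config`` (including its seed): candidate scoring
    order follows the feature universe, and score ties go to the lowest
    universe index.
    """
    universe = collection.feature_universe
    if config.n_select > len(universe):
        raise ValueError(
            f"n_select={config.n_select} exceeds the {len(universe)}-bit universe"
        )
    prepared = _prepare_targets(collection)
    rng = np.random.default_rng(config.seed)

    selected: list[int] = []
    remaining = list(range(len(universe)))
    aic_trace: list[float] = []
    per_target_trace: list[dict[str, float]] = []

    for step in range(config.n_select):
        if config.subsample_size is not None and len(selected) > config.subsample_size:
            context = sorted(
                rng.choice(selected, size=config.subsample_size, replace=False).tolist()
            )
        else:
            context = list(selected)

        # compact context pattern per target, computed once per iteration
        ctx_codes = []
        for values, labels, se, _ in prepared:
            if context:
                ctx_codes.append(_joint_codes(values[:, context]))
            else:
                ctx_codes.append(np.zeros(values.shape[0], dtype=np.int64))

        best_j, best_score = None, -1.0
        for j in remaining:
            score = 0.0
            for (values, labels, se, _), ctx in zip(prepared, ctx_codes):
                cand = ctx * 2 + values[:, j]
                score += min(_mi_bits(cand, labels) / se, 1.0)
            score /= len(prepared)
            if score > best_score + _TIE_TOL:
                best_score, best_j = score, j

        selected.append(best_j)
        remaining.remove(best_j)
        aic, per_target = _aic_indices(prepared, selected)
        aic_trace.append(aic)
        per_target_trace.append(per_target)
        logger.info(
            "step=%d selected=%s aic=%.6f", step + 1, universe[best_j], aic
        )

    return SelectionResult(
        selected=[universe[j] for j in selected],
        aic_trace=aic_trace,
        per_target_trace=per_target_trace,
        config=config,
    )


def exhaustive_best_subset(
    collection: TargetCollection, size: int, guard: int = 10**6
) -> SelectionResult:
    """Globally optimal subset of the given size by full enumeration.

    Intended as an oracle on small instances; refuses instances with more
    than ``guard`` candidate subsets.  Ties go to the lexicographically
    smallest index tuple.
    """
    universe = collection.feature_universe
    p = len(universe)
    if not 1 <= size <= p:
        raise ValueError(f"size must be in [1, {p}]")
    n_subsets = math.comb(p, size)
    if n_subsets > guard:
        raise ValueError(
            f"{n_subsets} subsets exceed the enumeration guard ({guard}); "
            "use aic_max_select instead"
        )
    prepared = _prepare_targets(collection)

    best_combo, best_aic = None, -1.0
    for combo in itertools.combinations(range(p), size):
        aic, _ = _aic_indices(prepared, combo)
        if aic > best_aic + _TIE_TOL:
            best_aic, best_combo = aic, combo

    aic_trace, per_target_trace = [], []
    for s in range(1, size + 1):
        aic, per_target = _aic_indices(prepared, best_combo[:s])
        aic_trace.append(aic)
        per_target_trace.append(per_target)
    return SelectionResult(
        selected=[universe[j] for j in best_combo],
        aic_trace=aic_trace,
        per_target_trace=per_target_trace,
        config=SelectionConfig(n_select=size, subsample_size=None, seed=0),
    )


def selection_result_from_features(
    collection: TargetCollection, feature_ids: Sequence[str]
) -> SelectionResult:
    """Rebuild a result (with exact traces) from an ordered feature list."""
    prepared = _prepare_targets(collection)
    indices = collection.activity_sets[0].matrix.column_indices(feature_ids)
    aic_trace, per_target_trace = [], []
    for s in range(1, len(indices) + 1):
        aic, per_target = _aic_indices(prepared, indices[:s])
        aic_trace.append(aic)
        per_target_trace.append(per_target)
    return SelectionResult(
        selected=list(feature_ids),
        aic_trace=aic_trace,
        per_target_trace=per_target_trace,
        config=SelectionConfig(n_select=max(len(indices), 1), subsample_size=None),
    )


def information_curve(
    collection: TargetCollection,
    result: SelectionResult,
    prefix_sizes: Sequence[int],
) -> pd.DataFrame:
    """Exact per-target normalized MI of selection prefixes.

    Returns a frame indexed by prefix size with one column per target plus a
    ``mean`` column (the AIC).  Size 0 is allowed and scores 0 everywhere.
    """
    prepared = _prepare_targets(collection)
    matrix = collection.activity_sets[0].matrix
    indices = matrix.column_indices(result.selected)
    rows = {}
    for s in prefix_sizes:
        if not 0 <= s <= len(indices):
            raise ValueError(
                f"prefix size {s} out of range [0, {len(indices)}]"
            )
        if s == 0:
            per_target = {tid: 0.0 for _, _, _, tid in prepared}
            aic = 0.0
        else:
            aic, per_target = _aic_indices(prepared, indices[:s])
        rows[s] = {**per_target, "mean": aic}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "n_bits"
    return frame
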