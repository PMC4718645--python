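"""Core data containers for multi-target binary fingerprint datasets.

A :class:`BitMatrix` holds a compounds x features 0/1 matrix with stable
string feature identifiers (conventionally ``"<fingerprint>:<bit-index>"``,
e.g. ``"pubchem:647"``, so that a bit's provenance survives hybridization).
An :class:`ActivitySet` pairs one target's matrix with its binary activity
labels, and a :class:`TargetCollection` binds several targets over one shared
feature universe.  Compound sets may differ between targets: a ligand needs a
measured label for only one receptor to contribute.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = ["BitMatrix", "ActivitySet", "TargetCollection"]


def _as_binary_array(values, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name}: no observations")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1)")
    return arr.astype(np.uint8)


def _check_unique(ids: Sequence[str], what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        raise ValueError(f"duplicate {what}: {sorted(set(dupes))}")
    return ids


@dataclass
class BitMatrix:
    """Compounds x features binary matrix with named rows and columns.

    Parameters
    ----------
    values
        0/1 matrix, one row per compound, one column per feature.
    feature_ids
        Unique feature names, one per column.  Order is significant: it
        defines the universe order used for deterministic tie-breaking.
    compound_ids
        Unique compound names, one per row.
    pattern_descriptions
        Optional free-text substructure description per feature id (for
        non-hashed fingerprint bits whose patterns are known).
    """

    values: np.ndarray
    feature_ids: list[str]
    compound_ids: list[str]
    pattern_descriptions: Mapping[str, str] | None = None
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.values = _as_binary_array(self.values, "bit matrix", 2)
        self.feature_ids = _check_unique(self.feature_ids, "feature_ids")
        self.compound_ids = _check_unique(self.compound_ids, "compound_ids")
        n, m = self.values.shape
        if len(self.feature_ids) != m:
            raise ValueError(
                f"{len(self.feature_ids)} feature_ids for {m} columns"
            )
        if len(self.compound_ids) != n:
            raise ValueError(
                f"{len(self.compound_ids)} compound_ids for {n} rows"
            )
        self._index = {f: j for j, f in enumerate(self.feature_ids)}

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def column_indices(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Column positions of the given feature ids, in the given order."""
        try:
            return np.array([self._index[f] for f in feature_ids], dtype=np.intp)
        except KeyError as exc:
            raise ValueError(f"unknown feature_id: {exc.args[0]!r}") from None

    def columns(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Dense 0/1 sub-matrix of the selected features."""
        return self.values[:, self.column_indices(feature_ids)]

    def rows(self, mask: np.ndarray) -> "BitMatrix":
        """Row subset by boolean mask, preserving order."""
        mask = np.asarray(mask, dtype=bool)
        return BitMatrix(
            self.values[mask],
            list(self.feature_ids),
            [c for c, keep in zip(self.compound_ids, mask) if keep],
            self.pattern_descriptions,
        )


@dataclass
class ActivitySet:
    """One target's bit matrix plus per-compound binary activity labels.

    ``labels[i] == 1`` marks compound *i* as active against ``target_id``;
    0 marks a confirmed or putative inactive.
    """

    matrix: BitMatrix
    labels: np.ndarray
    target_id: str

    def __post_init__(self) -> None:
        self.labels = _as_binary_array(self.labels, "labels", 1)
        if len(self.labels) != self.matrix.n_compounds:
            raise ValueError(
                f"target {self.target_id!r}: {len(self.labels)} labels for "
                f"{self.matrix.n_compounds} compounds"
            )
        self.target_id = str(self.target_id)

    @property
    def n_compounds(self) -> int:
        return self.matrix.n_compounds

    def subset(self, mask: np.ndarray) -> "ActivitySet":
        """Compound subset by boolean mask (used for CV folds)."""
        mask = np.asarray(mask, dtype=bool)
        return ActivitySet(self.matrix.rows(mask), self.labels[mask], self.target_id)


@dataclass
class TargetCollection:
    """K activity sets sharing one feature universe; compound sets may differ."""

    activity_sets: list[ActivitySet]

    def __post_init__(self) -> None:
        if len(self.activity_sets) < 1:
            raise ValueError("a collection needs at least one target")
        _check_unique([a.target_id for a in self.activity_sets], "target_ids")
        universe = self.activity_sets[0].matrix.feature_ids
        for a in self.activity_sets[1:]:
            if a.matrix.feature_ids != universe:
                raise ValueError(
                    f"target {a.target_id!r} does not share the feature universe "
                    f"of target {self.activity_sets[0].target_id!r}"
                )

    @property
    def feature_universe(self) -> list[str]:
        return list(self.activity_sets[0].matrix.feature_ids)

    @property
    def n_targets(self) -> int:
        return len(self.activity_sets)

    @property
    def target_ids(self) -> list[str]:
        return [a.target_id for a in self.activity_sets]

    def __iter__(self):
        return iter(self.activity_sets)
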