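"""Readers and writers for bit matrices, manifests and selection reports.

Two on-disk encodings are supported for a bit matrix:

* ``dense`` — a CSV whose first column holds compound ids, whose header row
  holds feature ids, and whose cells are 0/1;
* ``sparse`` — a triplet CSV with columns ``compound_id, feature_id, value``
  listing only the set bits (value must be 1; absent cells are 0).  Hybrid
  fingerprint matrices are mostly zeros, so this is the compact form.

A JSON *manifest* binds several targets to one shared feature universe:

.. code-block:: json

    {"feature_universe": ["estate:1", "..."],  // or "infer"
     "dialect": "dense",
     "targets": [{"target_id": "5-HT2A",
                  "matrix_path": "5ht2a.csv",
                  "labels_path": "5ht2a_labels.csv"}]}

Labels come either from a two-column CSV (``compound_id, label``) via
``labels_path`` or, for dense matrices, from a named column of the matrix
file via ``labels_column``.  Relative paths resolve against the manifest's
directory.  With ``"feature_universe": "infer"`` the first target's matrix
defines the universe and every other matrix must match it exactly.

Selection reports pair a CSV (one row per selected bit with its provenance
and the exact information trace) with a JSON sidecar recording the
configuration, seed and SHA-256 digests of the inputs, which is enough to
reproduce the run.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .data import ActivitySet, BitMatrix, TargetCollection
from .selection import SelectionResult
from .synthetic import GroundTruth, SyntheticSpec

__all__ = [
    "read_bit_matrix",
    "write_bit_matrix",
    "read_labels",
    "write_labels",
    "load_collection",
    "write_collection",
    "write_selection_report",
    "read_selection_report",
    "write_cv_scores",
    "synthetic_spec_from_json",
]


def _read_dense_frame(path) -> pd.DataFrame:
    path = Path(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh), None)
    if not header or len(header) < 2:
        raise ValueError(f"{path}: dense matrix needs an id column and a header row")
    features = header[1:]
    if len(set(features)) != len(features):
        raise ValueError(f"{path}: duplicate feature ids in header")
    df = pd.read_csv(path, index_col=0)
    df.columns = features  # undo any pandas mangling of odd names
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"{path}: duplicate compound ids {dupes}")
    return df


def _frame_to_matrix(df: pd.DataFrame, path) -> BitMatrix:
    num = df.apply(pd.to_numeric, errors="coerce")
    bad = ~num.isin([0, 1])
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-binary cell at compound {df.index[i]!r}, "
            f"feature {df.columns[j]!r}: {df.iat[i, j]!r}"
        )
    return BitMatrix(
        num.to_numpy(dtype=np.uint8),
        feature_ids=[str(c) for c in df.columns],
        compound_ids=list(df.index),
    )


def _read_sparse(path, feature_universe: Sequence[str] | None) -> BitMatrix:
    path = Path(path)
    df = pd.read_csv(path, dtype={"compound_id": str, "feature_id": str})
    required = {"compound_id", "feature_id", "value"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: sparse triplet file needs columns {sorted(required)}"
        )
    bad = df[~df["value"].isin([1])]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"{path}: sparse cells must have value 1; got {row['value']!r} at "
            f"compound {row['compound_id']!r}, feature {row['feature_id']!r}"
        )
    compounds = list(dict.fromkeys(df["compound_id"]))
    if feature_universe is None:
        features = list(dict.fromkeys(df["feature_id"]))
    else:
        features = list(feature_universe)
        unknown = sorted(set(df["feature_id"]) - set(features))
        if unknown:
            raise ValueError(f"{path}: feature ids outside the universe: {unknown}")
    fidx = {f: j for j, f in enumerate(features)}
    cidx = {c: i for i, c in enumerate(compounds)}
    values = np.zeros((len(compounds), len(features)), dtype=np.uint8)
    values[
        df["compound_id"].map(cidx).to_numpy(),
        df["feature_id"].map(fidx).to_numpy(),
    ] = 1
    return BitMatrix(values, feature_ids=features, compound_ids=compounds)


def read_bit_matrix(
    path, dialect: str = "dense", feature_universe: Sequence[str] | None = None
) -> BitMatrix:
    """Read a bit matrix from a dense CSV or a sparse triplet CSV.

    For the sparse dialect an explicit ``feature_universe`` fixes the column
    set and order (all-zero columns cannot be inferred from triplets alone).
    """
    if dialect == "dense":
        return _frame_to_matrix(_read_dense_frame(path), path)
    if dialect == "sparse":
        return _read_sparse(path, feature_universe)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'dense' or 'sparse')")


def write_bit_matrix(matrix: BitMatrix, path, dialect: str = "dense") -> None:
    path = Path(path)
    if dialect == "dense":
        df = pd.DataFrame(
            matrix.values, index=matrix.compound_ids, columns=matrix.feature_ids
        )
        df.index.name = "compound_id"
        df.to_csv(path)
    elif dialect == "sparse":
        rows, cols = np.nonzero(matrix.values)
        pd.DataFrame(
            {
                "compound_id": [matrix.compound_ids[i] for i in rows],
                "feature_id": [matrix.feature_ids[j] for j in cols],
                "value": 1,
            }
        ).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_labels(path) -> dict[str, int]:
    df = pd.read_csv(path, dtype={"compound_id": str})
    if not {"compound_id", "label"}.issubset(df.columns):
        raise ValueError(f"{path}: labels file needs columns compound_id, label")
    if df["compound_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate compound ids in labels file")
    return dict(zip(df["compound_id"], df["label"].astype(int)))


def write_labels(activity: ActivitySet, path) -> None:
    pd.DataFrame(
        {"compound_id": activity.matrix.compound_ids, "label": activity.labels}
    ).to_csv(path, index=False)


def _align_labels(matrix: BitMatrix, mapping: dict[str, int], origin) -> np.ndarray:
    missing = [c for c in matrix.compound_ids if c not in mapping]
    if missing:
        raise ValueError(f"{origin}: no label for compounds {missing[:5]}")
    return np.array([mapping[c] for c in matrix.compound_ids])


def load_collection(manifest_path) -> TargetCollection:
    """Load a multi-target collection described by a JSON manifest."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    targets = manifest.get("targets", [])
    if not targets:
        raise ValueError(f"{manifest_path}: manifest declares no targets")
    dialect = manifest.get("dialect", "dense")
    universe = manifest.get("feature_universe", "infer")
    explicit = universe != "infer"
    base = manifest_path.parent

    sets = []
    for entry in targets:
        tid = entry["target_id"]
        mpath = base / entry["matrix_path"]
        if dialect == "dense":
            df = _read_dense_frame(mpath)
            labels_map = None
            if "labels_column" in entry:
                col = entry["labels_column"]
                if col not in df.columns:
                    raise ValueError(f"{mpath}: no labels column {col!r}")
                labels = df[col].astype(int).to_numpy()
                df = df.drop(columns=[col])
            matrix = _frame_to_matrix(df, mpath)
            if "labels_column" not in entry:
                labels = _align_labels(
                    matrix, read_labels(base / entry["labels_path"]), mpath
                )
        else:
            matrix = _read_sparse(mpath, list(universe) if explicit else None)
            labels = _align_labels(
                matrix, read_labels(base / entry["labels_path"]), mpath
            )
        if not explicit:
            universe, explicit = matrix.feature_ids, True
        if matrix.feature_ids != list(universe):
            missing = sorted(set(universe) - set(matrix.feature_ids))
            extra = sorted(set(matrix.feature_ids) - set(universe))
            raise ValueError(
                f"target {tid!r}: feature universe mismatch "
                f"(missing {missing[:5]}, extra {extra[:5]})"
            )
        sets.append(ActivitySet(matrix, labels, tid))
    return TargetCollection(sets)


def write_collection(
    collection: TargetCollection,
    out_dir,
    dialect: str = "dense",
    ground_truth: GroundTruth | None = None,
) -> Path:
    """Write one matrix + labels CSV pair per target plus a manifest.

    Returns the manifest path; :func:`load_collection` round-trips it.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for a in collection.activity_sets:
        stem = a.target_id.replace("/", "_").replace(" ", "_")
        matrix_name, labels_name = f"{stem}_matrix.csv", f"{stem}_labels.csv"
        write_bit_matrix(a.matrix, out_dir / matrix_name, dialect=dialect)
        write_labels(a, out_dir / labels_name)
        entries.append(
            {
                "target_id": a.target_id,
                "matrix_path": matrix_name,
                "labels_path": labels_name,
            }
        )
    manifest = {
        "feature_universe": collection.feature_universe,
        "dialect": dialect,
        "targets": entries,
    }
    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    if ground_truth is not None:
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(
                {
                    "informative": ground_truth.informative,
                    "redundant": {
                        k: {"source": s, "negated": neg}
                        for k, (s, neg) in ground_truth.redundant.items()
                    },
                    "noise": ground_truth.noise,
                    "rules": {k: list(v) for k, v in ground_truth.rules.items()},
                },
                fh,
                indent=1,
            )
    return manifest_path


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _split_feature_id(feature_id: str) -> tuple[str, str]:
    if ":" in feature_id:
        fp, idx = feature_id.split(":", 1)
        if fp and idx:
            return fp, idx
    return "", ""


def write_selection_report(
    result: SelectionResult,
    collection: TargetCollection,
    path,
    input_paths: Sequence = (),
) -> Path:
    """Write the ranked selection as CSV plus a JSON provenance sidecar."""
    path = Path(path)
    descriptions = {}
    for a in collection.activity_sets:
        if a.matrix.pattern_descriptions:
            descriptions.update(a.matrix.pattern_descriptions)
    rows = []
    for rank, fid in enumerate(result.selected, start=1):
        fp, idx = _split_feature_id(fid)
        row = {
            "rank": rank,
            "feature_id": fid,
            "fingerprint": fp,
            "bit_index": idx,
            "pattern_description": descriptions.get(fid, ""),
            "aic_after_step": result.aic_trace[rank - 1],
        }
        for tid, value in result.per_target_trace[rank - 1].items():
            row[f"norm_mi_{tid}"] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")

    sidecar = {
        "config": {
            "n_select": result.config.n_select,
            "subsample_size": result.config.subsample_size,
            "seed": result.config.seed,
        },
        "selected": result.selected,
        "target_ids": collection.target_ids,
        "input_digests": {str(p): _sha256(p) for p in input_paths},
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return path


def read_selection_report(path) -> list[str]:
    """Ordered feature ids of a previously written selection report."""
    df = pd.read_csv(path)
    if "feature_id" not in df.columns:
        raise ValueError(f"{path}: not a selection report (no feature_id column)")
    return [str(f) for f in df["feature_id"]]


def write_cv_scores(per_fold: pd.DataFrame, path) -> None:
    """Per-fold CV scores as CSV (one row per target x fold)."""
    per_fold.to_csv(path, index=False, float_format="%.12g")


def synthetic_spec_from_json(path, seed: int | None = None) -> SyntheticSpec:
    """Build a :class:`SyntheticSpec` from a JSON parameter file."""
    with open(path) as fh:
        params = json.load(fh)
    if "activity_rules" in params and params["activity_rules"] is not None:
        params["activity_rules"] = tuple(tuple(r) for r in params["activity_rules"])
    if seed is not None:
        params["seed"] = seed
    try:
        return SyntheticSpec(**params)
    except TypeError as exc:
        raise ValueError(f"{path}: {exc}") from None
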