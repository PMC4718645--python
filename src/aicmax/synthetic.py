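"""Synthetic multi-target fingerprint datasets with planted ground truth.

Real selection studies draw actives from bioactivity databases and pad each
target with putative inactives (library decoys) at a fixed 9:1 ratio.  The
generator emulates that structure without any chemistry: each target gets
its own compound set whose activity is a deterministic boolean rule (an AND
over a couple of planted "informative" bits), optionally corrupted by label
noise; "redundant" bits are exact copies or negations of informative bits
(as happens when several fingerprint families encode the same substructure);
"noise" bits are independent of everything.  Putative inactives draw their
informative bits at a reduced prevalence, mimicking decoys being
structurally distinct from the active chemotype.

The returned :class:`GroundTruth` manifest names every planted bit and its
role, so recovery experiments can check that selection ranks planted (or
equivalent redundant) bits above noise.

Two exact 8-compound worked examples used throughout the documentation and
tests are packaged as :func:`table1_fixture` (three one-bit targets showing
the extreme values of the average information content) and
:func:`table2_fixture` (one target with Y = X1 AND X2 plus an irrelevant and
an anti-correlated bit).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .data import ActivitySet, BitMatrix, TargetCollection

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "generate_multitarget_data",
    "table1_fixture",
    "table2_fixture",
]

_MAX_REJECTION_ROUNDS = 200


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic multi-target dataset.

    Parameters
    ----------
    n_targets
        Number of biological targets K.
    n_actives
        Active compounds per target.
    inactive_ratio
        Label-0 compounds per active (default 9.0, the customary decoy
        ratio in virtual-screening benchmarks).
    n_informative_bits
        Planted bits that determine activity through the per-target rules.
    n_redundant_bits
        Exact copies/negations of informative bits (copy for even redundant
        index, negation for odd), cycling over the informative bits.
    n_noise_bits
        Bits independent of labels and of every other bit.
    activity_rules
        One rule per target: a tuple of informative-bit indices whose AND
        defines activity.  ``None`` assigns consecutive pairs
        ``(2i mod B, (2i+1) mod B)`` so the rules jointly cover all planted
        bits.
    bit_prevalence
        Bernoulli rate of each bit among actives (and of all noise bits).
    inactive_prevalence_factor
        Informative-bit prevalence among label-0 compounds is
        ``factor * bit_prevalence``; below 1 makes decoys structurally
        distinct from actives, so single planted bits already carry signal.
    label_noise
        Probability of flipping each compound's label after rule evaluation.
    seed
        Generator seed; identical specs produce identical collections.
    """

    n_targets: int = 3
    n_actives: int = 200
    inactive_ratio: float = 9.0
    n_informative_bits: int = 5
    n_redundant_bits: int = 10
    n_noise_bits: int = 85
    activity_rules: tuple[tuple[int, ...], ...] | None = None
    bit_prevalence: float = 0.5
    inactive_prevalence_factor: float = 0.5
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.n_actives < 1:
            raise ValueError("n_targets and n_actives must be >= 1")
        if self.n_informative_bits < 1:
            raise ValueError("at least one informative bit is required")
        if min(self.n_redundant_bits, self.n_noise_bits) < 0:
            raise ValueError("bit counts must be >= 0")
        if self.inactive_ratio < 0:
            raise ValueError("inactive_ratio must be >= 0")
        if not 0.0 < self.bit_prevalence < 1.0:
            raise ValueError("bit_prevalence must be in (0, 1)")
        if not 0.0 < self.inactive_prevalence_factor * self.bit_prevalence < 1.0:
            raise ValueError("inactive informative-bit prevalence out of (0, 1)")
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")

    def resolved_rules(self) -> list[tuple[int, ...]]:
        if self.activity_rules is None:
            b = self.n_informative_bits
            rules = []
            for i in range(self.n_targets):
                pair = (2 * i) % b, (2 * i + 1) % b
                rules.append(pair if pair[0] != pair[1] else (pair[0],))
            return rules
        rules = [tuple(r) for r in self.activity_rules]
        if len(rules) != self.n_targets:
            raise ValueError(
                f"{len(rules)} activity rules for {self.n_targets} targets"
            )
        for r in rules:
            if not r:
                raise ValueError("each activity rule needs at least one bit")
            if any(not 0 <= j < self.n_informative_bits for j in r):
                raise ValueError(
                    "activity rule references missing bits: "
                    f"{r} with {self.n_informative_bits} informative bits"
                )
        return rules


@dataclass
class GroundTruth:
    """Planted structure of a generated collection."""

    informative: list[str]
    redundant: dict[str, tuple[str, bool]]  # redundant id -> (source id, negated)
    noise: list[str]
    rules: dict[str, tuple[str, ...]]  # target id -> informative ids ANDed

    def equivalent_ids(self, informative_id: str) -> set[str]:
        """The informative bit together with its exact copies/negations."""
        ids = {informative_id}
        ids.update(
            rid for rid, (src, _) in self.redundant.items() if src == informative_id
        )
        return ids


def _sample_rule_conditioned(
    rng: np.random.Generator,
    n_rows: int,
    n_bits: int,
    prevalence: float,
    rule: tuple[int, ...],
    want: int,
) -> np.ndarray:
    """Informative-bit rows drawn at ``prevalence``, conditioned on the rule
    evaluating to ``want`` (rejection sampling)."""
    chunks, collected = [], 0
    batch = max(4 * n_rows, 256)
    for _ in range(_MAX_REJECTION_ROUNDS):
        rows = (rng.random((batch, n_bits)) < prevalence).astype(np.uint8)
        keep = rows[rows[:, list(rule)].min(axis=1) == want]
        chunks.append(keep)
        collected += len(keep)
        if collected >= n_rows:
            return np.concatenate(chunks)[:n_rows]
    raise ValueError(
        "impossible spec: activity rule almost never evaluates to "
        f"{want} at the requested prevalence"
    )


def generate_multitarget_data(
    spec: SyntheticSpec,
) -> tuple[TargetCollection, GroundTruth]:
    """Generate a multi-target collection with planted informative structure.

    Each target receives ``n_actives`` rule-positive compounds and
    ``round(inactive_ratio * n_actives)`` rule-negative compounds (then
    ``label_noise`` flips), sharing one universe ordered informative,
    redundant, noise.
    """
    rng = np.random.default_rng(spec.seed)
    rules = spec.resolved_rules()
    n_inf, n_red, n_noise = (
        spec.n_informative_bits,
        spec.n_redundant_bits,
        spec.n_noise_bits,
    )
    inf_ids = [f"informative:{j}" for j in range(n_inf)]
    red_ids = [f"redundant:{j}" for j in range(n_red)]
    noise_ids = [f"noise:{j}" for j in range(n_noise)]
    universe = inf_ids + red_ids + noise_ids
    red_map = {
        red_ids[j]: (inf_ids[j % n_inf], j % 2 == 1) for j in range(n_red)
    }

    n_inactives = int(round(spec.inactive_ratio * spec.n_actives))
    sets = []
    for t, rule in enumerate(rules):
        tid = f"T{t}"
        act = _sample_rule_conditioned(
            rng, spec.n_actives, n_inf, spec.bit_prevalence, rule, want=1
        )
        inact = _sample_rule_conditioned(
            rng,
            n_inactives,
            n_inf,
            spec.inactive_prevalence_factor * spec.bit_prevalence,
            rule,
            want=0,
        )
        informative = np.concatenate([act, inact])
        n = len(informative)
        labels = np.concatenate(
            [np.ones(spec.n_actives, dtype=np.uint8), np.zeros(n_inactives, dtype=np.uint8)]
        )
        if spec.label_noise > 0:
            flips = rng.random(n) < spec.label_noise
            labels = labels ^ flips.astype(np.uint8)

        redundant = np.empty((n, n_red), dtype=np.uint8)
        for j in range(n_red):
            src = informative[:, j % n_inf]
            redundant[:, j] = (1 - src) if j % 2 == 1 else src
        noise = (rng.random((n, n_noise)) < spec.bit_prevalence).astype(np.uint8)

        matrix = BitMatrix(
            np.concatenate([informative, redundant, noise], axis=1),
            feature_ids=list(universe),
            compound_ids=[f"{tid}:c{i:05d}" for i in range(n)],
        )
        sets.append(ActivitySet(matrix, labels, tid))

    truth = GroundTruth(
        informative=inf_ids,
        redundant=red_map,
        noise=noise_ids,
        rules={f"T{t}": tuple(inf_ids[j] for j in rule) for t, rule in enumerate(rules)},
    )
    return TargetCollection(sets), truth


def _eight_row_bits() -> np.ndarray:
    """All 2^3 bit patterns in ascending binary order (X1 most significant)."""
    return np.array(
        [[(i >> 2) & 1, (i >> 1) & 1, i & 1] for i in range(8)], dtype=np.uint8
    )


def table1_fixture() -> TargetCollection:
    """Three one-bit targets on a shared 8-compound, 3-bit matrix.

    Target Yi's activity equals bit Xi exactly, so a single bit fully
    determines one target (per-target score 1) and is independent of the
    other two (score 0); {X1, X2} over all three targets scores 2/3.
    """
    bits = _eight_row_bits()
    matrix = BitMatrix(
        bits,
        feature_ids=["X1", "X2", "X3"],
        compound_ids=[f"c{i + 1}" for i in range(8)],
    )
    return TargetCollection(
        [ActivitySet(matrix, bits[:, i], f"Y{i + 1}") for i in range(3)]
    )


def table2_fixture() -> TargetCollection:
    """One target, 8 compounds, 4 bits: Y = X1 AND X2, X4 = NOT(X1).

    X3 is independent of Y, and X4 is perfectly anti-correlated with X1, so
    neither changes the information carried jointly with X1 — the worked
    example behind the redundancy-invariance property.
    """
    bits = _eight_row_bits()
    x4 = (1 - bits[:, 0]).reshape(-1, 1)
    matrix = BitMatrix(
        np.concatenate([bits, x4], axis=1),
        feature_ids=["X1", "X2", "X3", "X4"],
        compound_ids=[f"c{i + 1}" for i in range(8)],
    )
    labels = bits[:, 0] & bits[:, 1]
    return TargetCollection([ActivitySet(matrix, labels, "Y")])
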