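"""Solute-out (API-out) structured group K-fold assignment.

Every record of a given solute lands in exactly one fold, so each fold model
is validated only on compounds it has never seen. "Structured" is realized as
balancing the total record count per fold: groups are placed largest-first
into the currently lightest fold, with a seeded shuffle breaking size ties,
which makes the assignment deterministic under a seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._seeds import derive_seed

__all__ = ["FoldAssignment", "AuditReport", "assign_folds", "audit_partition", "derive_seed"]


@dataclass(frozen=True)
class FoldAssignment:
    """Map from solute identity to fold index (0..k-1)."""

    k: int
    group_to_fold: dict[str, int]

    def __post_init__(self) -> None:
        folds = set(self.group_to_fold.values())
        if not folds <= set(range(self.k)):
            raise ValueError("fold indices out of range")
        if len(folds) != self.k:
            raise ValueError("every fold must be non-empty")

    def record_indices(self, groups: Sequence[str]) -> list[np.ndarray]:
        """Per-fold record index arrays for a record-aligned group-label sequence."""
        groups = np.asarray(groups)
        missing = set(np.unique(groups)) - set(self.group_to_fold)
        if missing:
            raise KeyError(f"groups without fold assignment: {sorted(missing)}")
        fold_of = np.array([self.group_to_fold[g] for g in groups])
        return [np.flatnonzero(fold_of == f) for f in range(self.k)]

    def to_json(self) -> str:
        return json.dumps({"k": self.k, "group_to_fold": self.group_to_fold}, sort_keys=True)


def assign_folds(group_sizes: Mapping[str, int], k: int, seed: int) -> FoldAssignment:
    """Greedy largest-first bin packing of solute groups into k folds.

    Groups are sorted by decreasing record count; ties are ordered by a seeded
    shuffle. Each group goes to the fold with the smallest running record
    total (ties broken by fold index). Deterministic given the seed.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    names = sorted(group_sizes)
    if k > len(names):
        raise ValueError(f"k={k} exceeds number of groups ({len(names)})")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(names))
    order = sorted(perm, key=lambda g: -int(group_sizes[g]))  # stable: shuffled within size ties

    totals = [0] * k
    mapping: dict[str, int] = {}
    for g in order:
        f = int(np.argmin(totals))
        mapping[g] = f
        totals[f] += int(group_sizes[g])
    return FoldAssignment(k=k, group_to_fold=mapping)


@dataclass(frozen=True)
class AuditReport:
    passed: bool
    problems: tuple[str, ...]


def audit_partition(assignment: FoldAssignment, groups: Sequence[str]) -> AuditReport:
    """Verify partition invariants on a record-aligned group-label sequence.

    Checks: every solute assigned, exactly one fold per solute, every fold
    non-empty, per-fold record sets disjoint and jointly exhaustive.
    """
    problems: list[str] = []
    groups = np.asarray(groups)
    present = set(np.unique(groups))
    unassigned = present - set(assignment.group_to_fold)
    for g in sorted(unassigned):
        problems.append(f"solute {g!r} has no fold assignment")

    if not unassigned:
        index_sets = assignment.record_indices(groups)
        seen: dict[int, int] = {}
        for f, idx in enumerate(index_sets):
            if idx.size == 0:
                problems.append(f"fold {f} holds no records")
            for i in idx:
                if i in seen:
                    problems.append(
                        f"record {int(i)} (solute {groups[i]!r}) appears in folds {seen[i]} and {f}"
                    )
                seen[int(i)] = f
        if len(seen) != groups.size:
            problems.append("per-fold record sets do not cover all records")
    return AuditReport(passed=not problems, problems=tuple(problems))
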