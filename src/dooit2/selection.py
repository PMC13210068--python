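"""Multi-run champion selection and feature-selection stability.

The whole fold-specific workflow is repeated several times with independent
seeds. A champion run is then chosen in two stages: architectural-stability
filtering (the run's representative descriptor count must recur in at least
30% of runs, and the smallest recurring count wins) followed by a composite
score over the eligible runs weighting predictive accuracy 50%, explanatory
power (R^2) 30% and the train-test performance gap 20%.

Reproducibility of feature selection is quantified as the mean pairwise
Jaccard similarity of the runs' selected feature sets:

    stability = 2 / (k (k-1)) * sum_{i<j} |F_i ∩ F_j| / |F_i ∪ F_j|
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seeds import derive_seed
from .dataset import DescriptorTable
from .engine import EngineSettings, FoldEnsemble, train_fold_ensemble
from .folds import assign_folds
from .metrics import mae, r2, rmsd

__all__ = [
    "RunResult",
    "ChampionSelection",
    "stability",
    "architectural_stability",
    "composite_score",
    "run_protocol",
]


@dataclass
class RunResult:
    """Pooled outcome of one independent workflow run."""

    run_index: int
    fold_feature_sets: tuple[frozenset, ...]
    fold_counts: tuple[int, ...]
    test_mae: float
    test_rmsd: float
    test_r2: float
    train_mae: float
    ensemble: FoldEnsemble | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if tuple(len(s) for s in self.fold_feature_sets) != tuple(self.fold_counts):
            raise ValueError("fold_counts must equal feature-set sizes")
        for v in (self.test_mae, self.test_rmsd, self.test_r2, self.train_mae):
            if not np.isfinite(v):
                raise ValueError("run metrics must be finite")

    @property
    def representative_count(self) -> float:
        """The run's descriptor count: median of its fold-level counts."""
        return float(np.median(self.fold_counts))

    @property
    def union_feature_set(self) -> frozenset:
        """The run-level feature set F_i: union of its fold-selected sets."""
        return frozenset().union(*self.fold_feature_sets)


@dataclass(frozen=True)
class ChampionSelection:
    stable_count: float
    eligible_run_indices: tuple[int, ...]
    scores: dict[int, float]
    champion_run_index: int
    stability_eligible: float
    stability_all: float

    def __post_init__(self) -> None:
        if self.champion_run_index not in self.eligible_run_indices:
            raise ValueError("champion must be among the eligible runs")
        for v in (self.stability_eligible, self.stability_all):
            if not (0.0 <= v <= 1.0 + 1e-12):
                raise ValueError("stability must lie in [0, 1]")


def stability(feature_sets) -> float:
    """Mean pairwise Jaccard similarity of the selected feature sets."""
    sets = [frozenset(s) for s in feature_sets]
    if len(sets) < 2:
        raise ValueError("stability requires at least two feature sets")
    if any(len(s) == 0 for s in sets):
        raise ValueError("stability undefined for empty feature sets")
    k = len(sets)
    total = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            total += len(sets[i] & sets[j]) / len(sets[i] | sets[j])
    return 2.0 * total / (k * (k - 1))


def architectural_stability(
    runs: list[RunResult], threshold: float = 0.30
) -> tuple[float, list[RunResult]]:
    """Filter runs by recurring descriptor count.

    A representative count is architecturally stable when it appears in at
    least ``threshold`` of the runs; the smallest stable count is selected
    and the runs showing it become eligible for champion scoring.
    """
    if not runs:
        raise ValueError("no runs")
    counts = [r.representative_count for r in runs]
    uniq, freq = np.unique(counts, return_counts=True)
    stable = uniq[freq / len(runs) >= threshold]
    if stable.size == 0:
        raise ValueError(
            "no descriptor count recurs in at least "
            f"{threshold:.0%} of runs; increase the number of independent runs"
        )
    stable_count = float(stable.min())
    eligible = [r for r in runs if r.representative_count == stable_count]
    return stable_count, eligible


def _norm_higher_better(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:  # degenerate: all runs identical on this criterion
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def _norm_lower_better(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values)
    return (hi - values) / (hi - lo)


def composite_score(eligible: list[RunResult]) -> tuple[dict[int, float], RunResult]:
    """Score eligible runs (0.5 accuracy + 0.3 R^2 + 0.2 generalization gap).

    Each raw criterion is min-max normalized over the eligible set so that
    higher is better; the champion is the argmax, ties resolved by lower test
    MAE then lower run index.
    """
    if not eligible:
        raise ValueError("no eligible runs")
    test_mae = np.array([r.test_mae for r in eligible])
    test_r2 = np.array([r.test_r2 for r in eligible])
    gap = np.abs(np.array([r.train_mae for r in eligible]) - test_mae)
    score = (
        0.5 * _norm_lower_better(test_mae)
        + 0.3 * _norm_higher_better(test_r2)
        + 0.2 * _norm_lower_better(gap)
    )
    scores = {r.run_index: float(s) for r, s in zip(eligible, score)}
    champion = min(
        zip(eligible, score), key=lambda pair: (-pair[1], pair[0].test_mae, pair[0].run_index)
    )[0]
    return scores, champion


def run_protocol(
    table: DescriptorTable,
    settings: EngineSettings = EngineSettings(),
    n_runs: int = 15,
    seed: int = 0,
    keep_ensembles: bool = True,
) -> tuple[ChampionSelection, list[RunResult]]:
    """Repeat the fold-specific workflow ``n_runs`` times and pick a champion.

    Each run derives its own seed from the master seed and re-draws the
    solute-out fold partition, so runs are fully independent given the data.
    """
    runs: list[RunResult] = []
    for r_idx in range(n_runs):
        run_seed = derive_seed(seed, r_idx)
        assignment = assign_folds(table.group_sizes(), settings.k, run_seed)
        ens = train_fold_ensemble(table, assignment, settings, run_seed)
        y = table.df["log_x_exp"].to_numpy(dtype=float)
        sets = tuple(ens.fold_feature_sets())
        runs.append(
            RunResult(
                run_index=r_idx,
                fold_feature_sets=sets,
                fold_counts=tuple(len(s) for s in sets),
                test_mae=mae(y, ens.oof_predictions),
                test_rmsd=rmsd(y, ens.oof_predictions),
                test_r2=r2(y, ens.oof_predictions),
                train_mae=float(np.mean([m.train_mae for m in ens.fold_models])),
                ensemble=ens if keep_ensembles else None,
            )
        )

    stable_count, eligible = architectural_stability(runs)
    scores, champion = composite_score(eligible)
    selection = ChampionSelection(
        stable_count=stable_count,
        eligible_run_indices=tuple(r.run_index for r in eligible),
        scores=scores,
        champion_run_index=champion.run_index,
        stability_eligible=(
            stability([r.union_feature_set for r in eligible]) if len(eligible) >= 2 else 1.0
        ),
        stability_all=(
            stability([r.union_feature_set for r in runs]) if len(runs) >= 2 else 1.0
        ),
    )
    return selection, runs
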