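"""Core correction-model workflow.

For each solute-out fold, the workflow searches gradient-boosted-tree
hyperparameters under two objectives (cross-validated MAE and model
complexity), selects a candidate from the Pareto front with the
one-standard-error rule, ranks features by permutation importance, prunes the
least informative feature, and repeats down to a minimum feature count. The
physics-based baseline column is exempt from pruning: the learned model is a
correction around it, never a replacement.

The per-fold pipeline runs only on the records of the other folds; out-of-fold
predictions for the held-out solutes are therefore genuinely out-of-sample
with respect to compound identity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seeds import derive_seed
from .dataset import BASELINE_NAME, DescriptorTable, assemble_features
from .folds import FoldAssignment, assign_folds, audit_partition
from .metrics import mae as _mae
from .models import (
    DEFAULT_SPACE,
    FittedModel,
    ModelConfig,
    SearchSpace,
    complexity as model_complexity,
    make_train_data,
    train_model,
)

__all__ = [
    "Candidate",
    "ParetoFront",
    "PruningLevel",
    "PruningTrace",
    "FittedPipeline",
    "EngineSettings",
    "FoldModel",
    "FoldEnsemble",
    "inner_cv_mae",
    "dual_objective_search",
    "pareto_nondominated",
    "one_se_select",
    "permutation_importance",
    "iterative_pruning",
    "select_level",
    "train_fold_ensemble",
    "predict",
]

INNER_K = 5  # inner grouped CV folds inside the optimization loop


@dataclass(frozen=True)
class Candidate:
    """One evaluated configuration: accuracy, dispersion and complexity."""

    trial: int
    config: ModelConfig
    feature_names: tuple[str, ...]
    cv_mae: float
    cv_mae_se: float
    complexity: float

    def __post_init__(self) -> None:
        if self.cv_mae < 0 or self.complexity < 0:
            raise ValueError("cv_mae and complexity must be non-negative")


@dataclass(frozen=True)
class ParetoFront:
    candidates: tuple[Candidate, ...]

    def __post_init__(self) -> None:
        for p in self.candidates:
            for q in self.candidates:
                if p is q:
                    continue
                if (
                    q.cv_mae <= p.cv_mae
                    and q.complexity <= p.complexity
                    and (q.cv_mae < p.cv_mae or q.complexity < p.complexity)
                ):
                    raise ValueError("front contains a dominated candidate")


class _Standardizer:
    """Column-wise zero-mean unit-variance scaling fit on training data only."""

    def __init__(self, X: np.ndarray):
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0  # constant columns pass through centred
        self.scale = sd

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


class _InnerEvaluator:
    """Shared inner-CV state for one pruning level.

    The five grouped inner splits, their standardizers and the family-native
    training containers are built once and reused across every trial of the
    level's search.
    """

    def __init__(
        self, X: np.ndarray, y: np.ndarray, groups, family: str, seed: int, max_bin: int = 255
    ):
        groups = np.asarray(groups)
        sizes: dict[str, int] = {}
        for g in groups:
            sizes[g] = sizes.get(g, 0) + 1
        if len(sizes) < INNER_K:
            raise ValueError(
                f"inner {INNER_K}-fold CV requires at least {INNER_K} solute groups, got {len(sizes)}"
            )
        assignment = assign_folds(sizes, INNER_K, seed)
        self.family = family
        self.splits = []
        for val_idx in assignment.record_indices(groups):
            mask = np.ones(len(y), dtype=bool)
            mask[val_idx] = False
            scaler = _Standardizer(X[mask])
            data = make_train_data(family, scaler.transform(X[mask]), y[mask], max_bin=max_bin)
            X_val = scaler.transform(X[val_idx])
            self.splits.append((data, X_val, y[val_idx]))

    def evaluate(self, config: ModelConfig) -> tuple[list[float], FittedModel]:
        maes = []
        first_model = None
        for data, X_val, y_val in self.splits:
            model = train_model(config, data)
            if first_model is None:
                first_model = model
            maes.append(_mae(y_val, model.predict(X_val)))
        return maes, first_model


def inner_cv_mae(config: ModelConfig, X, y, groups, seed: int) -> tuple[float, float]:
    """Mean and standard error (sd/sqrt(5)) of inner grouped 5-fold MAEs."""
    X = np.asarray(X, dtype=float)
    ev = _InnerEvaluator(
        X, np.asarray(y, dtype=float), groups, config.family, seed, max_bin=config.max_bin
    )
    maes, _ = ev.evaluate(config)
    return float(np.mean(maes)), float(np.std(maes, ddof=1) / np.sqrt(len(maes)))


def dual_objective_search(
    X: pd.DataFrame,
    y,
    groups,
    family: str = "lightgbm",
    n_trials: int = 100,
    seed: int = 0,
    space: SearchSpace = DEFAULT_SPACE,
) -> list[Candidate]:
    """Sample ``n_trials`` configurations and record (CV-MAE, complexity).

    The sampler draws configurations from the declared space with a seeded
    generator, so identical inputs and seed reproduce the identical trial
    sequence. Complexity is measured on the first inner-fold model of each
    trial (realized tree depths vary little across inner folds).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    feature_names = tuple(X.columns)
    Xa = X.to_numpy(dtype=float)
    ya = np.asarray(y, dtype=float)
    ev = _InnerEvaluator(Xa, ya, groups, family, derive_seed(seed, 0), max_bin=space.max_bin)
    rng = np.random.default_rng(derive_seed(seed, 1))
    out: list[Candidate] = []
    for t in range(n_trials):
        config = space.sample(rng, family, seed=derive_seed(seed, 2, t))
        maes, model = ev.evaluate(config)
        out.append(
            Candidate(
                trial=t,
                config=config,
                feature_names=feature_names,
                cv_mae=float(np.mean(maes)),
                cv_mae_se=float(np.std(maes, ddof=1) / np.sqrt(len(maes))),
                complexity=model_complexity(model),
            )
        )
    return out


def pareto_nondominated(candidates: list[Candidate]) -> ParetoFront:
    """The non-dominated subset in (cv_mae, complexity), minimizing both.

    Exact duplicates on both objectives keep only the earliest trial.
    """
    if not candidates:
        raise ValueError("no candidates")
    front: list[Candidate] = []
    best_cx = np.inf
    for c in sorted(candidates, key=lambda c: (c.cv_mae, c.complexity, c.trial)):
        if c.complexity < best_cx:
            front.append(c)
            best_cx = c.complexity
    front.sort(key=lambda c: c.trial)
    return ParetoFront(tuple(front))


def one_se_select(candidates) -> Candidate:
    """The one-standard-error rule: simplest model within one SE of the best.

    The threshold is best CV-MAE plus the SE of the best candidate's fold
    MAEs; among candidates under the threshold the least complex wins, ties
    resolved by lower CV-MAE then earlier trial.
    """
    if isinstance(candidates, ParetoFront):
        candidates = candidates.candidates
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidates")
    best = min(candidates, key=lambda c: (c.cv_mae, c.trial))
    threshold = best.cv_mae + best.cv_mae_se
    eligible = [c for c in candidates if c.cv_mae <= threshold + 1e-12]
    return min(eligible, key=lambda c: (c.complexity, c.cv_mae, c.trial))


@dataclass
class FittedPipeline:
    """Standardizer + trained booster over a fixed, ordered feature list."""

    feature_names: tuple[str, ...]
    scaler: _Standardizer = field(repr=False)
    model: FittedModel = field(repr=False)

    @classmethod
    def fit(cls, X: pd.DataFrame, y, config: ModelConfig) -> "FittedPipeline":
        Xa = X.to_numpy(dtype=float)
        scaler = _Standardizer(Xa)
        data = make_train_data(
            config.family, scaler.transform(Xa), np.asarray(y, dtype=float), max_bin=config.max_bin
        )
        return cls(tuple(X.columns), scaler, train_model(config, data))

    def predict(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = set(self.feature_names) - set(X.columns)
            if missing:
                raise KeyError(f"missing feature column(s): {sorted(missing)}")
            X = X[list(self.feature_names)].to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
        return self.model.predict(self.scaler.transform(X))


def permutation_importance(
    pipeline: FittedPipeline,
    X: pd.DataFrame,
    y,
    n_repeats: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Per-feature MAE degradation when the feature column is shuffled.

    importance_f = mean over repeats of (MAE with column f permuted) minus
    the unpermuted MAE; all permutations come from one seeded generator and
    are drawn independently per (feature, repeat).
    """
    missing = set(pipeline.feature_names) - set(X.columns)
    if missing:
        raise KeyError(f"unknown feature(s): {sorted(missing)}")
    ya = np.asarray(y, dtype=float)
    Xs = pipeline.scaler.transform(X[list(pipeline.feature_names)].to_numpy(dtype=float))
    base = _mae(ya, pipeline.model.predict(Xs))
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for j, name in enumerate(pipeline.feature_names):
        deg = 0.0
        for _ in range(n_repeats):
            Xp = Xs.copy()
            Xp[:, j] = Xp[rng.permutation(len(ya)), j]
            deg += _mae(ya, pipeline.model.predict(Xp)) - base
        out[name] = deg / n_repeats
    return out


@dataclass(frozen=True)
class PruningLevel:
    feature_names: tuple[str, ...]
    candidate: Candidate
    importances: dict[str, float]


@dataclass(frozen=True)
class PruningTrace:
    levels: tuple[PruningLevel, ...]
    baseline_name: str = BASELINE_NAME

    def __post_init__(self) -> None:
        for prev, cur in zip(self.levels, self.levels[1:]):
            removed = set(prev.feature_names) - set(cur.feature_names)
            added = set(cur.feature_names) - set(prev.feature_names)
            if len(removed) != 1 or added:
                raise ValueError("consecutive levels must differ by exactly one removed feature")
        for level in self.levels:
            if self.baseline_name not in level.feature_names:
                raise ValueError("baseline feature must never be pruned")


def iterative_pruning(
    X: pd.DataFrame,
    y,
    groups,
    family: str = "lightgbm",
    n_trials: int = 100,
    min_features: int = 3,
    seed: int = 0,
    space: SearchSpace = DEFAULT_SPACE,
    baseline_name: str = BASELINE_NAME,
    n_permutation_repeats: int = 10,
) -> PruningTrace:
    """Backward feature pruning driven by search, 1-SE selection and importances.

    At each level: dual-objective search on the current feature set, Pareto
    reduction, 1-SE selection, refit of the selected configuration on all
    provided records, permutation importance, and removal of the least
    important non-baseline feature. The loop stops at ``min_features``.
    """
    if min_features < 2:
        raise ValueError("min_features must be at least 2")
    if baseline_name not in X.columns:
        raise ValueError(f"baseline column {baseline_name!r} absent from features")
    features = list(X.columns)
    if len(features) <= min_features:
        raise ValueError("need more features than min_features to prune")

    # zero-variance descriptors carry no signal and break standardization scale
    dead = [c for c in features if c != baseline_name and float(np.std(X[c])) == 0.0]
    if dead:
        warnings.warn(f"dropping zero-variance feature(s) before search: {dead}")
        features = [c for c in features if c not in dead]

    levels: list[PruningLevel] = []
    level_idx = 0
    while True:
        lvl_seed = derive_seed(seed, level_idx)
        cands = dual_objective_search(
            X[features], y, groups, family, n_trials, derive_seed(lvl_seed, 0), space
        )
        selected = one_se_select(pareto_nondominated(cands))
        pipe = FittedPipeline.fit(X[features], y, selected.config)
        imps = permutation_importance(
            pipe, X, y, n_repeats=n_permutation_repeats, seed=derive_seed(lvl_seed, 1)
        )
        levels.append(PruningLevel(tuple(features), selected, imps))
        if len(features) <= min_features:
            break
        removable = [f for f in features if f != baseline_name]
        drop = min(removable, key=lambda f: (imps[f], f))
        features = [f for f in features if f != drop]
        level_idx += 1
    return PruningTrace(tuple(levels), baseline_name=baseline_name)


def select_level(trace: PruningTrace) -> PruningLevel:
    """Collapse the per-level candidate family to one model per fold.

    A second one-standard-error rule across pruning levels, with the feature
    count as the simplicity axis: among levels whose CV-MAE is within one SE
    of the best level, the one with the fewest features wins (ties: lower
    CV-MAE, then later level).
    """
    best = min(trace.levels, key=lambda l: l.candidate.cv_mae)
    threshold = best.candidate.cv_mae + best.candidate.cv_mae_se
    eligible = [l for l in trace.levels if l.candidate.cv_mae <= threshold + 1e-12]
    return min(eligible, key=lambda l: (len(l.feature_names), l.candidate.cv_mae))


@dataclass(frozen=True)
class EngineSettings:
    """Configuration of the fold-specific correction workflow."""

    family: str = "lightgbm"
    feature_config: str | tuple[str, ...] = "set2"
    k: int = 5
    n_trials: int = 2000
    min_features: int = 3
    space: SearchSpace = DEFAULT_SPACE
    n_permutation_repeats: int = 10


@dataclass
class FoldModel:
    fold: int
    pipeline: FittedPipeline = field(repr=False)
    candidate: Candidate
    feature_names: tuple[str, ...]
    trace: PruningTrace = field(repr=False)
    train_mae: float
    oof_mae: float


@dataclass
class FoldEnsemble:
    """Five fold-specific models plus their out-of-fold predictions."""

    assignment: FoldAssignment
    fold_models: list[FoldModel]
    oof_predictions: np.ndarray
    groups: np.ndarray = field(repr=False)

    def fold_feature_sets(self) -> list[frozenset]:
        return [frozenset(m.feature_names) for m in self.fold_models]

    def predict(self, table: DescriptorTable) -> np.ndarray:
        """Predict log10 mole-fraction solubility for new records.

        Compounds held out during the run are routed to their own fold model;
        unseen compounds get the unweighted mean of all fold models.
        """
        df = table.df
        preds = np.empty(len(df))
        by_fold = self.assignment.group_to_fold
        fold_of = np.array([by_fold.get(s, -1) for s in df["solute"]])
        for f, m in enumerate(self.fold_models):
            idx = np.flatnonzero(fold_of == f)
            if idx.size:
                preds[idx] = m.pipeline.predict(df.iloc[idx])
        unseen = np.flatnonzero(fold_of == -1)
        if unseen.size:
            block = df.iloc[unseen]
            preds[unseen] = np.mean([m.pipeline.predict(block) for m in self.fold_models], axis=0)
        return preds


def train_fold_ensemble(
    table: DescriptorTable,
    assignment: FoldAssignment,
    settings: EngineSettings = EngineSettings(),
    seed: int = 0,
) -> FoldEnsemble:
    """Run the full pruning + selection pipeline independently per fold."""
    X, y, groups = assemble_features(table, settings.feature_config)
    audit = audit_partition(assignment, groups)
    if not audit.passed:
        raise ValueError("invalid fold assignment: " + "; ".join(audit.problems))

    fold_indices = assignment.record_indices(groups)
    oof = np.full(len(y), np.nan)
    fold_models: list[FoldModel] = []
    for f, val_idx in enumerate(fold_indices):
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[val_idx] = False
        train_groups = groups[train_mask]
        held_out = {g for g, ff in assignment.group_to_fold.items() if ff == f}
        if set(train_groups) & held_out:
            raise AssertionError(f"solute leakage into fold {f} training data")

        trace = iterative_pruning(
            X[train_mask],
            y[train_mask],
            train_groups,
            family=settings.family,
            n_trials=settings.n_trials,
            min_features=settings.min_features,
            seed=derive_seed(seed, 10 + f),
            space=settings.space,
            n_permutation_repeats=settings.n_permutation_repeats,
        )
        chosen = select_level(trace)
        pipe = FittedPipeline.fit(
            X.loc[train_mask, list(chosen.feature_names)], y[train_mask], chosen.candidate.config
        )
        oof[val_idx] = pipe.predict(X.iloc[val_idx])
        fold_models.append(
            FoldModel(
                fold=f,
                pipeline=pipe,
                candidate=chosen.candidate,
                feature_names=chosen.feature_names,
                trace=trace,
                train_mae=_mae(y[train_mask], pipe.predict(X[train_mask])),
                oof_mae=_mae(y[val_idx], oof[val_idx]),
            )
        )
    if np.isnan(oof).any():
        raise AssertionError("out-of-fold predictions must cover every record exactly once")
    return FoldEnsemble(assignment, fold_models, oof, groups)


def predict(ensemble: FoldEnsemble, table: DescriptorTable) -> np.ndarray:
    """Module-level alias for :meth:`FoldEnsemble.predict`."""
    return ensemble.predict(table)
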