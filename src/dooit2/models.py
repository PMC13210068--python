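"""Gradient-boosted tree regressors behind a uniform train/predict surface.

Two families are supported, mirroring the two dataset regimes the workflow
targets: LightGBM (structurally diverse solute sets) and XGBoost
(chemically homogeneous acid series). The native training APIs are used so
that pre-binned training data can be reused across the many trials of a
hyperparameter search.

Model complexity is the number of boosted trees multiplied by the mean
realized tree depth (the actual maximum root-to-leaf edge count of each
grown tree, which may be smaller than the depth limit).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

import lightgbm as lgb
import xgboost as xgb

__all__ = [
    "FAMILIES",
    "ModelConfig",
    "SearchSpace",
    "DEFAULT_SPACE",
    "FAST_SPACE",
    "TrainData",
    "FittedModel",
    "make_train_data",
    "train_model",
    "complexity",
]

FAMILIES = ("lightgbm", "xgboost")


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one gradient-boosted tree ensemble."""

    family: str
    n_estimators: int
    max_depth: int
    learning_rate: float
    subsample: float
    colsample: float
    min_child_samples: int
    seed: int = 0
    max_bin: int = 255

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ValueError("n_estimators and max_depth must be positive")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in (0, 1]")
        if not (0.0 < self.subsample <= 1.0 and 0.0 < self.colsample <= 1.0):
            raise ValueError("sampling fractions must lie in (0, 1]")

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class SearchSpace:
    """Hyperparameter ranges sampled during dual-objective optimization.

    Tree counts and learning rate are sampled log-uniformly, depth and
    min_child_samples uniformly on integers, sampling fractions uniformly.
    """

    n_estimators: tuple[int, int] = (50, 2000)
    max_depth: tuple[int, int] = (2, 12)
    learning_rate: tuple[float, float] = (1e-3, 0.3)
    subsample: tuple[float, float] = (0.5, 1.0)
    colsample: tuple[float, float] = (0.5, 1.0)
    min_child_samples: tuple[int, int] = (2, 20)
    max_bin: int = 255  # histogram resolution; fixed per space, not searched

    def sample(self, rng: np.random.Generator, family: str, seed: int = 0) -> ModelConfig:
        def log_int(lo, hi):
            return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))

        return ModelConfig(
            family=family,
            n_estimators=log_int(*self.n_estimators),
            max_depth=int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            learning_rate=float(
                np.exp(rng.uniform(np.log(self.learning_rate[0]), np.log(self.learning_rate[1])))
            ),
            subsample=float(rng.uniform(*self.subsample)),
            colsample=float(rng.uniform(*self.colsample)),
            min_child_samples=int(
                rng.integers(self.min_child_samples[0], self.min_child_samples[1] + 1)
            ),
            seed=seed,
            max_bin=self.max_bin,
        )


DEFAULT_SPACE = SearchSpace()

#: Desk-scale space for the reduced protocol used in the synthetic
#: experiments: small ensembles trained on a few hundred records. Column
#: subsampling is disabled: a hybrid correction model relies on the baseline
#: column being available to every tree, and on narrow tables (down to two
#: columns at the deepest pruning level) any feature_fraction below 1 forces
#: whole trees to grow without the baseline.
FAST_SPACE = SearchSpace(
    n_estimators=(10, 50),
    max_depth=(2, 3),
    learning_rate=(0.08, 0.35),
    subsample=(0.8, 1.0),
    colsample=(1.0, 1.0),
    min_child_samples=(3, 10),
    max_bin=63,
)


@dataclass
class TrainData:
    """Training matrix wrapped in the family's native container for reuse."""

    family: str
    n_rows: int
    handle: Any = field(repr=False)


def make_train_data(family: str, X: np.ndarray, y: np.ndarray, max_bin: int = 255) -> TrainData:
    """Wrap (X, y) for repeated training; LightGBM data is pre-binned once."""
    X = np.ascontiguousarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if family == "lightgbm":
        ds = lgb.Dataset(
            X, label=y, params={"verbose": -1, "feature_pre_filter": False, "max_bin": max_bin}
        )
        ds.construct()
        return TrainData("lightgbm", len(y), ds)
    if family == "xgboost":
        return TrainData("xgboost", len(y), xgb.DMatrix(X, label=y))
    raise ValueError(f"unknown model family {family!r}")


@dataclass
class FittedModel:
    """A trained booster with its configuration."""

    family: str
    booster: Any = field(repr=False)
    config: ModelConfig = None  # type: ignore[assignment]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.ascontiguousarray(X, dtype=np.float64)
        if self.family == "lightgbm":
            return np.asarray(self.booster.predict(X))
        return np.asarray(self.booster.predict(xgb.DMatrix(X)))


def train_model(config: ModelConfig, data: TrainData) -> FittedModel:
    """Train one booster on prepared data; single-threaded and seed-determined."""
    if config.family != data.family:
        raise ValueError("config family does not match training data")
    if config.family == "lightgbm":
        params = {
            "objective": "regression",
            "max_depth": config.max_depth,
            "num_leaves": min(2**config.max_depth, 128),
            "learning_rate": config.learning_rate,
            "bagging_fraction": config.subsample,
            "bagging_freq": 1,
            "feature_fraction": config.colsample,
            "min_data_in_leaf": config.min_child_samples,
            "num_threads": 1,
            "verbose": -1,
            "seed": config.seed,
            "max_bin": config.max_bin,
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            booster = lgb.train(params, data.handle, num_boost_round=config.n_estimators)
        return FittedModel("lightgbm", booster, config)
    params = {
        "objective": "reg:squarederror",
        "max_depth": config.max_depth,
        "eta": config.learning_rate,
        "subsample": config.subsample,
        "colsample_bytree": config.colsample,
        "min_child_weight": config.min_child_samples,
        "nthread": 1,
        "tree_method": "hist",
        "max_bin": config.max_bin,
        "verbosity": 0,
        "seed": config.seed,
    }
    booster = xgb.train(params, data.handle, num_boost_round=config.n_estimators)
    return FittedModel("xgboost", booster, config)


def _lgb_node_depth(node: dict) -> int:
    left = node.get("left_child")
    right = node.get("right_child")
    if left is None and right is None:
        return 0
    depths = [_lgb_node_depth(c) for c in (left, right) if c is not None]
    return 1 + max(depths)


def _xgb_node_depth(node: dict) -> int:
    children = node.get("children")
    if not children:
        return 0
    return 1 + max(_xgb_node_depth(c) for c in children)


def tree_depths(model: FittedModel) -> list[int]:
    """Realized maximum depth (root-to-leaf edges) of every boosted tree."""
    if model.family == "lightgbm":
        dump = model.booster.dump_model()
        return [_lgb_node_depth(t["tree_structure"]) for t in dump["tree_info"]]
    dumps = model.booster.get_dump(dump_format="json")
    return [_xgb_node_depth(json.loads(s)) for s in dumps]


def complexity(model: FittedModel) -> float:
    """Model complexity: number of trees times mean realized tree depth."""
    if model is None or getattr(model, "booster", None) is None:
        raise ValueError("complexity requires a trained model")
    depths = tree_depths(model)
    if not depths:
        raise ValueError("model holds no trees")
    return len(depths) * float(np.mean(depths))
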