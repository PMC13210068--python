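"""Prediction-quality metrics and residual / applicability-domain profiling.

All metrics operate on decadal-log mole-fraction solubilities: ``y`` are
experimental values, ``y_hat`` model predictions. Residuals follow the
convention ``predicted - experimental``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PredictionSet",
    "rmsd",
    "r2",
    "mae",
    "residual_profile",
]


@dataclass(frozen=True)
class PredictionSet:
    """Aligned experimental and predicted values, optionally with molecular weight."""

    y: np.ndarray
    y_hat: np.ndarray
    mol_weight: np.ndarray | None = None

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        y_hat = np.asarray(self.y_hat, dtype=float)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "y_hat", y_hat)
        if y.shape != y_hat.shape or y.ndim != 1:
            raise ValueError("y and y_hat must be 1-D arrays of equal length")
        if y.size < 1:
            raise ValueError("PredictionSet must hold at least one pair")
        if not (np.isfinite(y).all() and np.isfinite(y_hat).all()):
            raise ValueError("non-finite values in PredictionSet")
        if self.mol_weight is not None:
            mw = np.asarray(self.mol_weight, dtype=float)
            if mw.shape != y.shape:
                raise ValueError("mol_weight must align with y")
            object.__setattr__(self, "mol_weight", mw)


def _coerce(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(y, PredictionSet):
        return y.y, y.y_hat
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise ValueError("empty prediction set")
    return y, y_hat


def rmsd(y, y_hat=None) -> float:
    """Root mean square deviation sqrt(mean((y - y_hat)^2))."""
    y, y_hat = _coerce(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def mae(y, y_hat=None) -> float:
    """Mean absolute error mean(|y - y_hat|)."""
    y, y_hat = _coerce(y, y_hat)
    return float(np.mean(np.abs(y - y_hat)))


def r2(y, y_hat=None) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    Undefined (raises) for constant experimental values.
    """
    y, y_hat = _coerce(y, y_hat)
    if y.size < 2:
        raise ValueError("r2 requires at least two observations")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("r2 undefined for constant experimental values")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def residual_profile(
    ps: PredictionSet,
    covariate: str = "y",
    n_bins: int = 10,
) -> tuple[pd.DataFrame, bool]:
    """Dispersion of residuals (predicted - experimental) across a covariate.

    The covariate is either the experimental solubility itself (``"y"``) or
    molecular weight (``"mol_weight"``). Records are split into equal-count
    quantile bins; the table reports per-bin residual mean, SD and count.

    Returns the table and a flag that is True when the lowest covariate
    quartile shows a larger residual SD than the highest quartile — the
    signature of degraded reliability in the low-solubility region.
    """
    if covariate == "y":
        cov = ps.y
    elif covariate == "mol_weight":
        if ps.mol_weight is None:
            raise ValueError("mol_weight covariate requested but not provided")
        cov = ps.mol_weight
    else:
        raise ValueError(f"unknown covariate {covariate!r}")

    resid = ps.y_hat - ps.y
    df = pd.DataFrame({"cov": cov, "resid": resid})
    df["bin"] = pd.qcut(df["cov"].rank(method="first"), q=min(n_bins, len(df)), labels=False)
    table = (
        df.groupby("bin")
        .agg(
            cov_low=("cov", "min"),
            cov_high=("cov", "max"),
            resid_mean=("resid", "mean"),
            resid_sd=("resid", lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0),
            n=("resid", "size"),
        )
        .reset_index()
    )
    if int(table["n"].sum()) != len(df):
        raise AssertionError("quantile bins must partition all records")

    q25, q75 = np.quantile(cov, [0.25, 0.75])
    low = resid[cov <= q25]
    high = resid[cov >= q75]
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    flag = sd(low) > sd(high)
    return table, flag
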