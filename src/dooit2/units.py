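"""Shake-flask data reduction: calibration, LOD/LOQ and mole-fraction solubility.

Converts UV-derived concentrations of a saturated solution into mole-fraction
solubility using the measured solution density and the molar masses of the
solute and the two solvents, with solvent composition given as solute-free
mole fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "SaturationMeasurement",
    "MolarMasses",
    "fit_calibration",
    "lod_loq",
    "mole_fraction",
    "replicate_stats",
    "reduce_measurements",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear Beer-Lambert calibration A = slope * C + intercept (C in mg/mL)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    def concentration(self, absorbance: float) -> float:
        """Invert the calibration line: C = (A - intercept) / slope."""
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive to invert")
        return (absorbance - self.intercept) / self.slope


@dataclass(frozen=True)
class SaturationMeasurement:
    """One saturated-solution measurement at a given solvent composition."""

    conc_mg_per_ml: float  # solute concentration C, mg/mL
    density_g_per_ml: float  # saturated-solution density rho, g/mL
    x_cosolvent_prime: float  # solute-free mole fraction of the organic solvent

    def __post_init__(self) -> None:
        if self.conc_mg_per_ml < 0:
            raise ValueError("concentration must be non-negative")
        if self.density_g_per_ml <= 0:
            raise ValueError("density must be positive")
        if not (0.0 <= self.x_cosolvent_prime <= 1.0):
            raise ValueError("solute-free mole fraction must lie in [0, 1]")
        if 1000.0 * self.density_g_per_ml <= self.conc_mg_per_ml:
            raise ValueError("non-physical: solute mass exceeds solution mass")


@dataclass(frozen=True)
class MolarMasses:
    """Molar masses (g/mol) of the solute and the two solvents."""

    m_solute: float
    m_solvent_a: float  # organic cosolvent (the one x' refers to)
    m_solvent_b: float  # second solvent (typically water)

    def __post_init__(self) -> None:
        if min(self.m_solute, self.m_solvent_a, self.m_solvent_b) <= 0:
            raise ValueError("molar masses must be positive")


def fit_calibration(points) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, absorbance) pairs."""
    arr = np.asarray(points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("at least 3 (concentration, absorbance) pairs required")
    conc, absorb = arr[:, 0], arr[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("degenerate calibration: all concentrations equal")
    res = stats.linregress(conc, absorb)
    return CalibrationCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


def lod_loq(sigma_blank: float, slope: float) -> tuple[float, float]:
    """Limits of detection and quantification: (3.3 sigma/S, 10 sigma/S) in mg/mL."""
    if slope <= 0:
        raise ValueError("slope must be positive")
    if sigma_blank < 0:
        raise ValueError("blank standard deviation must be non-negative")
    return 3.3 * sigma_blank / slope, 10.0 * sigma_blank / slope


def mole_fraction(meas: SaturationMeasurement, masses: MolarMasses) -> float:
    """Mole-fraction solubility from concentration, density and composition.

    X = n_solute / (n_solute + n_solvent) with
    n_solute  = C / M_solute                        (C in g/L = mg/mL)
    n_solvent = (1000 rho - C) / (x' M_a + (1-x') M_b)

    1000 rho converts the density to g/L so solvent mass = solution mass minus
    dissolved solute mass per litre; the mean solvent molar mass uses the
    solute-free composition x'.
    """
    c = meas.conc_mg_per_ml
    solvent_mass = 1000.0 * meas.density_g_per_ml - c  # g per litre of solution
    if solvent_mass <= 0:
        raise ValueError("non-physical measurement: no solvent mass")
    n_solute = c / masses.m_solute
    m_mean = meas.x_cosolvent_prime * masses.m_solvent_a + (
        1.0 - meas.x_cosolvent_prime
    ) * masses.m_solvent_b
    n_solvent = solvent_mass / m_mean
    return n_solute / (n_solute + n_solvent)


def replicate_stats(values) -> tuple[float, float]:
    """Sample mean and sample SD (n-1 denominator) of replicate mole fractions."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("at least two replicates required")
    return float(arr.mean()), float(arr.std(ddof=1))


def reduce_measurements(
    df: pd.DataFrame,
    masses: MolarMasses,
    calibration: CalibrationCurve | None = None,
) -> pd.DataFrame:
    """Reduce replicate measurements to per-composition mean X and SD.

    Expects columns ``x_cosolvent_prime``, ``density_g_per_ml`` and either
    ``conc_mg_per_ml`` or ``absorbance`` (the latter requires a calibration
    curve). Returns one row per composition with ``x_mean`` and ``x_sd``.
    """
    work = df.copy()
    if "conc_mg_per_ml" not in work.columns:
        if calibration is None:
            raise ValueError("absorbance input requires a calibration curve")
        work["conc_mg_per_ml"] = work["absorbance"].map(calibration.concentration)
    work["X"] = [
        mole_fraction(
            SaturationMeasurement(row.conc_mg_per_ml, row.density_g_per_ml, row.x_cosolvent_prime),
            masses,
        )
        for row in work.itertuples()
    ]
    out = (
        work.groupby("x_cosolvent_prime")["X"]
        .agg(x_mean="mean", x_sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
        .reset_index()
    )
    return out
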