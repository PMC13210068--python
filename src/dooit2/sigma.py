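"""Sigma-profile condensation into the 12-bin HBD/HH/HBA descriptor block.

COSMO-RS sigma-profiles and sigma-potentials come as 61 points over the
screening-charge-density axis -0.03 ... +0.03 e/A^2 (step 0.001). For machine
learning they are condensed by averaging over 0.005-wide intervals into a
12-step function spanning three regions:

* HBD1-HBD4, hydrogen-bond donor, sigma in [-0.03, -0.01)
* HH1-HH4, hydrophobic, sigma in [-0.01, +0.01)
* HBA1-HBA4, hydrogen-bond acceptor, sigma in [+0.01, +0.03]

Bins are half-open on the left; the terminal grid point +0.03 is assigned to
HBA4, so HBA4 averages 6 grid points and every other bin 5 (61 points cannot
split evenly into 12 bins).

Descriptors are emitted for the solute (``API_``), the solvent mixture
(``mix_``) and their difference (``d_`` = solute - mixture).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "N_GRID",
    "BIN_LABELS",
    "SigmaProfile",
    "BinnedSigma",
    "make_grid",
    "bin_profile",
    "mixture_profile",
    "sigma_block",
    "read_profile",
    "write_profile",
]

N_GRID = 61
_SIGMA_MIN = -0.03
_SIGMA_MAX = 0.03
_BIN_WIDTH = 0.005

BIN_LABELS: tuple[str, ...] = tuple(
    f"{region}{i}" for region in ("HBD", "HH", "HBA") for i in range(1, 5)
)


def make_grid() -> np.ndarray:
    """The canonical 61-point charge-density grid, -0.03 to +0.03, step 0.001."""
    return np.linspace(_SIGMA_MIN, _SIGMA_MAX, N_GRID)


def _bin_index(grid: np.ndarray) -> np.ndarray:
    # half-open [low, low + 0.005); terminal +0.03 joins the last bin
    idx = np.floor((grid - _SIGMA_MIN) / _BIN_WIDTH + 1e-9).astype(int)
    return np.clip(idx, 0, 11)


@dataclass(frozen=True)
class SigmaProfile:
    """A 61-point curve over the charge-density grid (profile or potential)."""

    values: np.ndarray
    grid: np.ndarray = field(default_factory=make_grid)

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.shape != (N_GRID,) or values.shape != (N_GRID,):
            raise ValueError(f"sigma profile must have exactly {N_GRID} points")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("sigma grid must be strictly increasing")
        if abs(grid[0] - _SIGMA_MIN) > 1e-12 or abs(grid[-1] - _SIGMA_MAX) > 1e-12:
            raise ValueError("sigma grid must span -0.03 ... +0.03 e/A^2")


@dataclass(frozen=True)
class BinnedSigma:
    """The 12-bin condensation, ordered HBD1..HBD4, HH1..HH4, HBA1..HBA4."""

    bins: np.ndarray
    labels: tuple[str, ...] = BIN_LABELS

    def __post_init__(self) -> None:
        bins = np.asarray(self.bins, dtype=float)
        object.__setattr__(self, "bins", bins)
        if bins.shape != (12,):
            raise ValueError("exactly 12 bin values required")
        if self.labels != BIN_LABELS:
            raise ValueError("bin label order is fixed")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.labels, map(float, self.bins)))


def bin_profile(profile: SigmaProfile) -> BinnedSigma:
    """Average the 61 values over the 12 half-open 0.005-wide intervals."""
    idx = _bin_index(profile.grid)
    sums = np.bincount(idx, weights=profile.values, minlength=12)
    counts = np.bincount(idx, minlength=12)
    return BinnedSigma(sums / counts)


def mixture_profile(profiles: list[SigmaProfile], fractions) -> SigmaProfile:
    """Mole-fraction-weighted convex combination of per-solvent profiles.

    A surrogate for the full COSMO-RS mixture treatment: pointwise linear
    mixing on a shared grid, with solute-free mole fractions summing to 1.
    """
    fractions = np.asarray(fractions, dtype=float)
    if len(profiles) != fractions.size or len(profiles) == 0:
        raise ValueError("one fraction per profile required")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    grid = profiles[0].grid
    for p in profiles[1:]:
        if not np.allclose(p.grid, grid, rtol=0, atol=1e-12):
            raise ValueError("profiles must share a common grid")
    mixed = np.zeros(N_GRID)
    for w, p in zip(fractions, profiles):
        mixed += w * p.values
    return SigmaProfile(mixed, grid=grid)


def sigma_block(
    solute_bins: BinnedSigma,
    mixture_bins: BinnedSigma,
    relative: bool = False,
) -> dict[str, float]:
    """The 36 named descriptors: solute, mixture and difference per bin label.

    ``d_<label>`` is the signed difference solute - mixture by default; with
    ``relative=True`` it is normalized by the mixture magnitude
    (solute - mixture) / (|mixture| + 1e-12).
    """
    out: dict[str, float] = {}
    for label, s, m in zip(BIN_LABELS, solute_bins.bins, mixture_bins.bins):
        out[f"API_{label}"] = float(s)
        out[f"mix_{label}"] = float(m)
        d = s - m
        if relative:
            d = d / (abs(m) + 1e-12)
        out[f"d_{label}"] = float(d)
    return out


def read_profile(path) -> SigmaProfile:
    """Read a two-column (sigma, value) text file; '#' lines are comments.

    Columns may be whitespace- or comma-delimited.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"malformed sigma-profile line: {line!r}")
        rows.append((float(parts[0]), float(parts[1])))
    if len(rows) != N_GRID:
        raise ValueError(f"expected {N_GRID} grid points, found {len(rows)}")
    arr = np.asarray(rows, dtype=float)
    return SigmaProfile(arr[:, 1], grid=arr[:, 0])


def write_profile(profile: SigmaProfile, path) -> None:
    lines = ["# sigma(e/A^2)  value"]
    for s, v in zip(profile.grid, profile.values):
        lines.append(f"{s:.6f} {v:.12g}")
    Path(path).write_text("\n".join(lines) + "\n")
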