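"""Descriptor-table model, I/O, curation and feature assembly.

The central dataset is one row per (solute, binary solvent pair, solute-free
composition, temperature) with the experimental decadal-log mole-fraction
solubility as target, the physics-based reference-solvent prediction
(``RefSol``) as immutable baseline column, and arbitrary named numeric
descriptor columns.

CSV dialect: comma-separated, dot decimal, UTF-8, mandatory header. Required
headers: ``solute, solvent_a, solvent_b, x_cosolvent, temperature_K,
log_x_exp, RefSol``. Optional metadata columns ``mol_weight`` and ``source``
are carried through but never treated as descriptors; every other numeric
column is a descriptor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "DescriptorSchema",
    "DescriptorTable",
    "read_table",
    "write_table",
    "canonicalize_solvent_pair",
    "canonicalize",
    "deduplicate",
    "CurationReport",
    "assemble_features",
]

REQUIRED_COLUMNS = (
    "solute",
    "solvent_a",
    "solvent_b",
    "x_cosolvent",
    "temperature_K",
    "log_x_exp",
    "RefSol",
)
METADATA_COLUMNS = ("mol_weight", "source")
BASELINE_NAME = "RefSol"

# sigma-potential block prefixes; columns with these prefixes belong to the
# Set 2 extension, everything else numeric is an energetic/chemical-potential
# (Set 1) descriptor
_SIGMA_PREFIXES = ("API_", "mix_", "d_")


class SchemaError(ValueError):
    """A required column is missing or the schema is inconsistent."""


@dataclass(frozen=True)
class DescriptorSchema:
    """Named descriptor configurations.

    ``set1_names`` hold the energetic / chemical-potential descriptors;
    ``set2_names`` extend them with the sigma-potential bin block. The
    baseline column is always separate and is prepended to every feature
    matrix.
    """

    set1_names: tuple[str, ...]
    set2_names: tuple[str, ...]
    baseline_name: str = BASELINE_NAME

    def __post_init__(self) -> None:
        if not set(self.set1_names) <= set(self.set2_names):
            raise SchemaError("set1 must be a subset of set2")
        if self.baseline_name in self.set2_names:
            raise SchemaError("baseline column must be distinct from descriptors")

    @classmethod
    def infer(cls, descriptor_names, baseline_name: str = BASELINE_NAME) -> "DescriptorSchema":
        names = tuple(descriptor_names)
        set1 = tuple(n for n in names if not n.startswith(_SIGMA_PREFIXES))
        return cls(set1_names=set1, set2_names=names, baseline_name=baseline_name)


@dataclass(frozen=True)
class DescriptorTable:
    """Validated solubility dataset with aligned descriptor columns."""

    df: pd.DataFrame
    schema: DescriptorSchema = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        object.__setattr__(self, "df", df)
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"missing required column: {col!r}")
        for col in ("x_cosolvent", "temperature_K", "log_x_exp", "RefSol"):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = np.flatnonzero(vals.isna().to_numpy())
            if bad.size:
                raise ValueError(f"non-numeric value in column {col!r} at row {int(bad[0])}")
            df[col] = vals.astype(float)
        if ((df["x_cosolvent"] < -1e-12) | (df["x_cosolvent"] > 1 + 1e-12)).any():
            raise ValueError("x_cosolvent must lie in [0, 1]")
        if (df["temperature_K"] <= 0).any():
            raise ValueError("temperature must be positive (kelvin)")
        if (df["log_x_exp"] > 1e-9).any():
            raise ValueError("log_x_exp must be <= 0 (mole fraction <= 1)")
        if not np.isfinite(df["RefSol"]).all():
            raise ValueError("RefSol baseline must be finite")
        if self.schema is None:
            object.__setattr__(self, "schema", DescriptorSchema.infer(self._descriptor_columns(df)))
        else:
            missing = set(self.schema.set2_names) - set(df.columns)
            if missing:
                raise SchemaError(f"schema names missing from table: {sorted(missing)}")

    @staticmethod
    def _descriptor_columns(df: pd.DataFrame) -> list[str]:
        reserved = set(REQUIRED_COLUMNS) | set(METADATA_COLUMNS)
        return [c for c in df.columns if c not in reserved and pd.api.types.is_numeric_dtype(df[c])]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def descriptor_names(self) -> tuple[str, ...]:
        return self.schema.set2_names

    def group_labels(self) -> np.ndarray:
        return self.df["solute"].to_numpy()

    def group_sizes(self) -> dict[str, int]:
        return self.df["solute"].value_counts().to_dict()

    def key_frame(self) -> pd.DataFrame:
        """The (solute, canonical solvent pair, composition, temperature) key."""
        return self.df[["solute", "solvent_a", "solvent_b", "x_cosolvent", "temperature_K"]]


def read_table(path, column_map: dict[str, str] | None = None) -> DescriptorTable:
    """Read and validate a descriptor table from CSV.

    ``column_map`` optionally renames source headers to the required names,
    e.g. ``{"compound": "solute"}``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return DescriptorTable(df)


def write_table(table: DescriptorTable, path) -> None:
    table.df.to_csv(path, index=False)


def canonicalize_solvent_pair(
    solvent_a: str, solvent_b: str, x_cosolvent: float
) -> tuple[str, str, float]:
    """Put a solvent pair into fixed case-insensitive lexicographic order.

    If the pair is swapped, the composition (solute-free mole fraction of the
    first solvent) is replaced by its complement 1 - x.
    """
    a, b = solvent_a.strip(), solvent_b.strip()
    if not a or not b:
        raise ValueError("solvent names must be non-empty")
    if b.casefold() < a.casefold():
        return b, a, 1.0 - x_cosolvent
    return a, b, x_cosolvent


def canonicalize(table: DescriptorTable) -> DescriptorTable:
    """Apply the canonical solvent-pair order to every record."""
    df = table.df.copy()
    canon = [
        canonicalize_solvent_pair(a, b, x)
        for a, b, x in zip(df["solvent_a"], df["solvent_b"], df["x_cosolvent"])
    ]
    df["solvent_a"] = [c[0] for c in canon]
    df["solvent_b"] = [c[1] for c in canon]
    df["x_cosolvent"] = [c[2] for c in canon]
    return DescriptorTable(df, schema=table.schema)


@dataclass(frozen=True)
class CurationReport:
    rows_in: int
    rows_out: int
    merged_groups: tuple[dict, ...]
    flagged_groups: tuple[dict, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "rows_in": self.rows_in,
                "rows_out": self.rows_out,
                "merged_groups": list(self.merged_groups),
                "flagged_groups": list(self.flagged_groups),
            },
            sort_keys=True,
        )


def deduplicate(
    table: DescriptorTable,
    tol_x: float = 1e-3,
    tol_T: float = 0.25,
    spread_threshold: float = 0.3,
) -> tuple[DescriptorTable, CurationReport]:
    """Merge near-duplicate records measured at comparable conditions.

    Within each (solute, canonical solvent pair), records are clustered
    greedily in (x, T) order: a record joins the current cluster when both
    |dx| <= tol_x and |dT| <= tol_T relative to the cluster's first member.
    Consistent clusters collapse to their first row with the mean target;
    clusters whose target spread (max - min) exceeds ``spread_threshold`` log
    units are flagged and kept unmerged. The table must be canonicalized
    first. The procedure is idempotent.
    """
    df = table.df
    keep_rows: list[pd.Series] = []
    merged: list[dict] = []
    flagged: list[dict] = []

    for (solute, sa, sb), grp in df.groupby(["solute", "solvent_a", "solvent_b"], sort=True):
        grp = grp.sort_values(["x_cosolvent", "temperature_K"], kind="mergesort")
        clusters: list[list[int]] = []
        ref_x = ref_t = None
        for idx, row in grp.iterrows():
            if (
                ref_x is not None
                and abs(row["x_cosolvent"] - ref_x) <= tol_x
                and abs(row["temperature_K"] - ref_t) <= tol_T
            ):
                clusters[-1].append(idx)
            else:
                clusters.append([idx])
                ref_x, ref_t = row["x_cosolvent"], row["temperature_K"]
        for members in clusters:
            if len(members) == 1:
                keep_rows.append(df.loc[members[0]])
                continue
            targets = df.loc[members, "log_x_exp"]
            spread = float(targets.max() - targets.min())
            info = {
                "solute": solute,
                "solvent_a": sa,
                "solvent_b": sb,
                "x_cosolvent": float(df.loc[members[0], "x_cosolvent"]),
                "size": len(members),
                "target_spread": spread,
            }
            if spread > spread_threshold:
                flagged.append(info)
                keep_rows.extend(df.loc[m] for m in members)
            else:
                rep = df.loc[members[0]].copy()
                rep["log_x_exp"] = float(targets.mean())
                keep_rows.append(rep)
                merged.append(info)

    out_df = pd.DataFrame(keep_rows).reset_index(drop=True)
    out = DescriptorTable(out_df, schema=table.schema)
    report = CurationReport(
        rows_in=len(df), rows_out=len(out_df), merged_groups=tuple(merged), flagged_groups=tuple(flagged)
    )
    return out, report


def assemble_features(
    table: DescriptorTable, config: str | list[str] = "set2"
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Build the feature matrix, target vector and solute group labels.

    ``config`` is ``"set1"``, ``"set2"`` or an explicit descriptor-name list.
    The baseline column is always included as the first matrix column; the
    remaining columns follow the requested order.
    """
    schema = table.schema
    if config == "set1":
        names = list(schema.set1_names)
    elif config == "set2":
        names = list(schema.set2_names)
    elif isinstance(config, str):
        raise ValueError(f"unknown feature configuration {config!r}")
    else:
        names = [n for n in config if n != schema.baseline_name]
        unknown = set(names) - set(schema.set2_names)
        if unknown:
            raise KeyError(f"unknown descriptor name(s): {sorted(unknown)}")
    cols = [schema.baseline_name] + names
    X = table.df[cols].astype(float).copy()
    y = table.df["log_x_exp"].to_numpy(dtype=float)
    groups = table.group_labels()
    return X, y, groups
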