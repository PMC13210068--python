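"""Table I/O, solvent-pair canonicalization, deduplication and feature assembly."""

import numpy as np
import pandas as pd
import pytest

from dooit2 import (
    DescriptorTable,
    SchemaError,
    SynthConfig,
    assemble_features,
    canonicalize,
    canonicalize_solvent_pair,
    deduplicate,
    generate_dataset,
    read_table,
    write_table,
)


def small_frame():
    return pd.DataFrame(
        {
            "solute": ["a", "a", "b"],
            "solvent_a": ["dmso", "dmso", "ethanol"],
            "solvent_b": ["water", "water", "water"],
            "x_cosolvent": [0.0, 0.5, 1.0],
            "temperature_K": [298.15] * 3,
            "log_x_exp": [-3.0, -2.5, -4.0],
            "RefSol": [-3.0, -2.4, -4.1],
            "E1_vdW_sat": [0.1, 0.2, 0.3],
            "d_HH2": [1.0, 2.0, 3.0],
        }
    )


def test_read_table_roundtrip(tmp_path):
    path = tmp_path / "t.csv"
    small_frame().to_csv(path, index=False)
    table = read_table(path)
    assert len(table) == 3
    out = tmp_path / "out.csv"
    write_table(table, out)
    again = read_table(out)
    pd.testing.assert_frame_equal(table.df, again.df)


def test_read_table_missing_target_column(tmp_path):
    df = small_frame().drop(columns=["log_x_exp"])
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(SchemaError, match="log_x_exp"):
        read_table(path)


def test_read_table_non_numeric_target_names_row(tmp_path):
    df = small_frame().astype({"log_x_exp": object})
    df.loc[1, "log_x_exp"] = "oops"
    path = tmp_path / "bad.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="row 1"):
        read_table(path)


def test_column_map_renames(tmp_path):
    df = small_frame().rename(columns={"solute": "compound"})
    path = tmp_path / "m.csv"
    df.to_csv(path, index=False)
    table = read_table(path, column_map={"compound": "solute"})
    assert list(table.df["solute"]) == ["a", "a", "b"]


def test_invariants_enforced():
    df = small_frame()
    df.loc[0, "log_x_exp"] = 0.5  # mole fraction above 1
    with pytest.raises(ValueError):
        DescriptorTable(df)
    df = small_frame()
    df.loc[0, "x_cosolvent"] = 1.2
    with pytest.raises(ValueError):
        DescriptorTable(df)


def test_canonicalize_solvent_pair():
    assert canonicalize_solvent_pair("water", "DMSO", 0.3) == ("DMSO", "water", 0.7)
    assert canonicalize_solvent_pair("DMSO", "water", 0.7) == ("DMSO", "water", 0.7)
    once = canonicalize_solvent_pair("water", "Ethanol", 0.25)
    assert canonicalize_solvent_pair(*once) == once  # idempotent


def test_schema_split_between_energetic_and_sigma_blocks():
    table = DescriptorTable(small_frame())
    assert "E1_vdW_sat" in table.schema.set1_names
    assert "d_HH2" not in table.schema.set1_names
    assert set(table.schema.set1_names) <= set(table.schema.set2_names)
    assert table.schema.baseline_name == "RefSol"


def test_deduplicate_merges_identical_rows():
    df = pd.concat([small_frame(), small_frame().iloc[[1]]], ignore_index=True)
    table = canonicalize(DescriptorTable(df))
    out, report = deduplicate(table)
    assert len(out) == 3
    assert report.rows_in == 4 and report.rows_out == 3
    assert len(report.merged_groups) == 1
    # merged row holds the mean target (identical here)
    assert out.df["log_x_exp"].tolist().count(-2.5) == 1


def test_deduplicate_respects_tolerance():
    df = small_frame()
    extra = df.iloc[[1]].copy()
    extra["x_cosolvent"] = 0.51
    df = pd.concat([df, extra], ignore_index=True)
    out, _ = deduplicate(canonicalize(DescriptorTable(df)), tol_x=0.001)
    assert len(out) == 4  # outside tolerance: both kept
    out2, _ = deduplicate(canonicalize(DescriptorTable(df)), tol_x=0.02)
    assert len(out2) == 3  # inside tolerance: merged


def test_deduplicate_flags_inconsistent_groups():
    df = small_frame()
    extra = df.iloc[[1]].copy()
    extra["log_x_exp"] = -1.5  # one full log unit apart
    df = pd.concat([df, extra], ignore_index=True)
    out, report = deduplicate(canonicalize(DescriptorTable(df)))
    assert len(out) == 4  # flagged, not merged
    assert len(report.flagged_groups) == 1


def test_curation_idempotent_and_shrinking_on_random_fixtures():
    rng = np.random.default_rng(0)
    for _ in range(500):
        n = int(rng.integers(3, 12))
        df = pd.DataFrame(
            {
                "solute": rng.choice(["a", "b"], size=n),
                "solvent_a": rng.choice(["dmso", "water"], size=n),
                "solvent_b": rng.choice(["water", "ethanol"], size=n),
                "x_cosolvent": rng.choice([0.0, 0.25, 0.5], size=n),
                "temperature_K": rng.choice([298.15, 303.15], size=n),
                "log_x_exp": np.round(rng.uniform(-5, -1, size=n), 2),
                "RefSol": rng.uniform(-5, -1, size=n),
            }
        )
        df = df[df.solvent_a != df.solvent_b].reset_index(drop=True)
        if len(df) < 2:
            continue
        table = DescriptorTable(df)
        once, _ = deduplicate(canonicalize(table))
        twice, rep2 = deduplicate(canonicalize(once))
        assert len(once) <= len(table)
        pd.testing.assert_frame_equal(once.df, twice.df)


def test_deduplicate_planted_duplicates_shrink_by_group_size():
    table, _ = generate_dataset(SynthConfig(n_solutes=4, seed=5))
    g = 4
    dup = pd.concat([table.df] + [table.df.iloc[[7]]] * (g - 1), ignore_index=True)
    out, report = deduplicate(canonicalize(DescriptorTable(dup)))
    assert len(out) == len(table.df)  # shrank by g - 1


def test_assemble_features_shapes_and_content():
    table, _ = generate_dataset(SynthConfig(n_solutes=4, seed=1))
    X1, y, groups = assemble_features(table, "set1")
    assert list(X1.columns)[0] == "RefSol"
    assert X1.shape[1] == 1 + len(table.schema.set1_names)
    X2, _, _ = assemble_features(table, "set2")
    assert X2.shape[1] == 1 + len(table.schema.set2_names)
    Xb, _, _ = assemble_features(table, ["RefSol"])
    assert Xb.shape[1] == 1
    assert np.allclose(Xb["RefSol"], table.df["RefSol"])
    # random-index spot check against direct lookup
    rng = np.random.default_rng(2)
    i = int(rng.integers(len(table)))
    for col in X2.columns:
        assert X2.iloc[i][col] == table.df.iloc[i][col]
    with pytest.raises(KeyError):
        assemble_features(table, ["no_such_descriptor"])


# --------------------------------------------------------------- properties
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

names = st.text(
    alphabet=st.characters(whitelist_categories=("Ll", "Lu")), min_size=1, max_size=8
)


@hyp_settings(max_examples=200, derandomize=True)
@given(a=names, b=names, x=st.floats(0, 1))
def test_canonicalize_pair_properties(a, b, x):
    ra, rb, rx = canonicalize_solvent_pair(a, b, x)
    assert {ra, rb} == {a.strip(), b.strip()}
    assert ra.casefold() <= rb.casefold()
    assert 0.0 <= rx <= 1.0
    assert canonicalize_solvent_pair(ra, rb, rx) == (ra, rb, rx)
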