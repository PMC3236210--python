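"""Readers and writers for the delimited-text and Newick interchange formats.

Presence matrices and overlap tables travel as comma-separated text with
a header row and the species id in the first column; biome columns are
canonicalized to the order I, II, II/III, III, IV, V, VI, VII, VIII, IX.
Trees travel as Newick with branch lengths preserved at full precision.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .catalog import BIOME_LABELS
from .coding import OVERLAP_COLUMNS, PresenceMatrix, validate_overlaps
from .speciation import PhyloDataset


class FormatError(ValueError):
    """Raised for malformed input files."""


def _read_csv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kw)
    except pd.errors.ParserError as err:
        raise FormatError(f"{path}: {err}") from err


def read_presence(path: str | Path) -> PresenceMatrix:
    df = _read_csv(path)
    if df.columns[0] != "species":
        raise FormatError(
            f"{path}: first column must be 'species', got {df.columns[0]!r}"
        )
    dup = df["species"][df["species"].duplicated()]
    if not dup.empty:
        raise FormatError(
            f"{path}: duplicate species id {dup.iloc[0]!r} "
            f"(line {int(dup.index[0]) + 2})"
        )
    df = df.set_index("species")
    missing = [b for b in BIOME_LABELS if b not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing biome columns {missing}")
    bio = df[list(BIOME_LABELS)]
    bad = ~bio.isin([0, 1, True, False]).all(axis=1)
    if bad.any():
        sp = bio.index[bad][0]
        raise FormatError(
            f"{path}: non-binary presence value for species {sp!r} "
            f"(line {int(np.flatnonzero(bad)[0]) + 2})"
        )
    clade = df["clade"] if "clade" in df.columns else None
    montane = df["montane"].astype(bool) if "montane" in df.columns else None
    return PresenceMatrix(data=bio.astype(bool), clade=clade, montane=montane)


def write_presence(matrix: PresenceMatrix, path: str | Path) -> None:
    out = matrix.data.astype(int).copy()
    if matrix.clade is not None:
        out["clade"] = matrix.clade
    if matrix.montane is not None:
        out["montane"] = matrix.montane.astype(int)
    out.to_csv(path, index_label="species")


def read_overlaps(path: str | Path) -> pd.DataFrame:
    df = _read_csv(path)
    missing = [c for c in OVERLAP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    for col in ("range_fraction", "dominion_fraction"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna())[0]) + 2
            raise FormatError(f"{path}: non-numeric {col} at line {line}")
        df[col] = vals
    return validate_overlaps(df)


def write_overlaps(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_tree(path: str | Path) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            path=str(path), schema="newick",
            preserve_underscores=True,
        )
    except Exception as err:
        raise FormatError(f"{path}: cannot parse Newick ({err})") from err


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick",
               suppress_rooting=True, unquoted_underscores=True,
               real_value_format_specifier=".17g")


def read_traits(path: str | Path,
                tree: Optional[dendropy.Tree] = None) -> pd.Series:
    """Two-column (species id, trait value) delimited text.

    With a tree given, the trait table must cover the tip set exactly;
    a missing or surplus tip is named in the error.
    """
    df = _read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (species, value)")
    sp_col, val_col = df.columns[0], df.columns[1]
    dup = df[sp_col][df[sp_col].duplicated()]
    if not dup.empty:
        raise FormatError(f"{path}: duplicate species id {dup.iloc[0]!r}")
    vals = pd.to_numeric(df[val_col], errors="coerce")
    if vals.isna().any():
        line = int(np.flatnonzero(vals.isna())[0]) + 2
        raise FormatError(f"{path}: non-numeric trait value at line {line}")
    traits = pd.Series(vals.to_numpy(), index=pd.Index(df[sp_col], name="species"),
                       name="trait")
    if tree is not None:
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        have = set(traits.index)
        if tips != have:
            missing = sorted(tips - have)
            extra = sorted(have - tips)
            msg = []
            if missing:
                msg.append(f"tips missing from trait file: {missing}")
            if extra:
                msg.append(f"trait rows not in tree: {extra}")
            raise FormatError(f"{path}: " + "; ".join(msg))
    return traits


def write_traits(traits: pd.Series, path: str | Path) -> None:
    traits.rename("trait").to_csv(path, index_label="species")


def read_phylo_dataset(tree_path: str | Path,
                       traits_path: str | Path) -> PhyloDataset:
    tree = read_tree(tree_path)
    traits = read_traits(traits_path, tree=tree)
    return PhyloDataset(tree=tree, traits=traits)
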