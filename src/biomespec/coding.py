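"""Biome coding: from range-dominion overlaps to presence matrix and BSI.

A species is recorded as present in a biome if at least 15% of its
geographic range lies within that biome (summing over the biome's
climatic dominions), or if it covers at least 50% of any single
dominion of that biome -- the latter rule rescues wide-ranging species
whose presence in a small dominion would otherwise fall below the 15%
cut.  Both comparisons are inclusive.

The biomic specialization index (BSI) of a species is the number of
biomes it inhabits (1-10 here).  Species are classed as stenobiomic
(BSI = 1), semi-eurybiomic (1 < BSI < 5) or extreme eurybiomic
(BSI >= 5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import BIOME_LABELS, BiomeCatalog, CatalogError

logger = logging.getLogger(__name__)

RANGE_THRESHOLD = 0.15      #: minimum fraction of the species range in a biome
DOMINION_THRESHOLD = 0.50   #: minimum coverage of a single climatic dominion

STENOBIOMIC = "stenobiomic"
SEMI_EURYBIOMIC = "semi-eurybiomic"
EXTREME_EURYBIOMIC = "extreme eurybiomic"

OVERLAP_COLUMNS = ("species", "dominion", "range_fraction", "dominion_fraction")


class OverlapError(ValueError):
    """Raised for invalid overlap tables."""


def validate_overlaps(overlaps: pd.DataFrame, tolerance: float = 1e-6) -> pd.DataFrame:
    """Validate an overlap table (long format, one row per species x dominion).

    Fractions must lie in [0, 1] and, per species, range fractions must not
    sum to more than 1 (+ tolerance).  Range fractions are deliberately NOT
    renormalized: a range may straddle area outside any cataloged dominion.
    """
    missing = [c for c in OVERLAP_COLUMNS if c not in overlaps.columns]
    if missing:
        raise OverlapError(f"overlap table missing columns: {', '.join(missing)}")
    for col in ("range_fraction", "dominion_fraction"):
        vals = overlaps[col].to_numpy(dtype=float)
        bad = ~((vals >= 0.0) & (vals <= 1.0))
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise OverlapError(
                f"{col} outside [0, 1] for species "
                f"{overlaps['species'].iloc[i]!r} (value {vals[i]!r})"
            )
    sums = overlaps.groupby("species")["range_fraction"].sum()
    over = sums[sums > 1.0 + tolerance]
    if not over.empty:
        sp = over.index[0]
        raise OverlapError(
            f"range fractions for species {sp!r} sum to {over.iloc[0]:.4f} > 1"
        )
    return overlaps


@dataclass
class AggregatedOverlaps:
    """Per-species, per-biome aggregates of the overlap table.

    ``range_fraction``      total fraction of the species range per biome
                            (montane analog dominions included);
    ``max_dominion_fraction``  largest single-dominion coverage per biome;
    ``*_nonmontane``        same quantities with montane dominions removed,
                            used to flag species whose presences depend on
                            mountain belts.
    """

    range_fraction: pd.DataFrame
    max_dominion_fraction: pd.DataFrame
    range_fraction_nonmontane: pd.DataFrame
    max_dominion_fraction_nonmontane: pd.DataFrame

    @property
    def species(self) -> pd.Index:
        return self.range_fraction.index


def aggregate_overlaps(
    catalog: BiomeCatalog, overlaps: pd.DataFrame
) -> AggregatedOverlaps:
    """Aggregate dominion-level overlaps to the biome level.

    Range fractions of dominions in the same biome are summed; the
    maximum single-dominion coverage per biome is retained (the 50% rule
    applies per dominion, never to pooled dominions).  Montane dominions
    contribute to their analog biome.
    """
    overlaps = validate_overlaps(overlaps)
    df = overlaps.copy()
    try:
        df["biome"] = [catalog.biome_of(d) for d in df["dominion"]]
    except CatalogError:
        raise
    df["montane"] = [catalog.is_montane(d) for d in df["dominion"]]

    species = pd.Index(pd.unique(df["species"]), name="species")

    def _pivot(sub: pd.DataFrame, how: str) -> pd.DataFrame:
        if sub.empty:
            out = pd.DataFrame(0.0, index=species, columns=list(BIOME_LABELS))
            out.columns.name = "biome"
            return out
        col = "range_fraction" if how == "sum" else "dominion_fraction"
        piv = sub.pivot_table(
            index="species", columns="biome", values=col, aggfunc=how, fill_value=0.0
        )
        piv = piv.reindex(index=species, columns=list(BIOME_LABELS), fill_value=0.0)
        return piv.astype(float)

    non = df[~df["montane"]]
    return AggregatedOverlaps(
        range_fraction=_pivot(df, "sum"),
        max_dominion_fraction=_pivot(df, "max"),
        range_fraction_nonmontane=_pivot(non, "sum"),
        max_dominion_fraction_nonmontane=_pivot(non, "max"),
    )


@dataclass
class PresenceMatrix:
    """Boolean species x biome matrix with optional per-species metadata.

    ``data`` has one row per retained species and the ten biome columns in
    canonical order.  ``clade`` (optional) labels each species with a clade
    name used for clade-restricted analyses; ``montane`` flags species any
    of whose presences derive only from montane analog dominions.
    """

    data: pd.DataFrame
    clade: Optional[pd.Series] = None
    montane: Optional[pd.Series] = None
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if list(self.data.columns) != list(BIOME_LABELS):
            self.data = self.data.reindex(columns=list(BIOME_LABELS))
            if self.data.isna().any().any():
                raise ValueError("presence matrix missing biome columns")
        self.data = self.data.astype(bool)
        self.data.columns.name = None
        self.data.index.name = "species"
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate species ids: {dups}")
        for name in ("clade", "montane"):
            s = getattr(self, name)
            if s is not None:
                s = s.reindex(self.data.index)
                if s.isna().any():
                    missing = s.index[s.isna()].tolist()
                    raise ValueError(f"{name} labels missing for: {missing}")
                setattr(self, name, s)

    @property
    def species(self) -> pd.Index:
        return self.data.index

    @property
    def n_species(self) -> int:
        return int(self.data.shape[0])

    @property
    def richness(self) -> pd.Series:
        """Per-biome species counts (the null model's fixed marginals)."""
        return self.data.sum(axis=0).astype(int)

    def subset(self, species: pd.Index | list[str]) -> "PresenceMatrix":
        keep = self.data.index.intersection(pd.Index(species))
        return PresenceMatrix(
            data=self.data.loc[keep],
            clade=None if self.clade is None else self.clade.loc[keep],
            montane=None if self.montane is None else self.montane.loc[keep],
        )

    def for_clade(self, clade: str) -> "PresenceMatrix":
        if self.clade is None:
            raise ValueError("presence matrix carries no clade labels")
        keep = self.clade.index[self.clade == clade]
        if len(keep) == 0:
            raise ValueError(f"no species with clade label {clade!r}")
        return self.subset(keep)


def code_presence(
    aggregated: AggregatedOverlaps,
    range_threshold: float = RANGE_THRESHOLD,
    dominion_threshold: float = DOMINION_THRESHOLD,
) -> PresenceMatrix:
    """Apply the two presence rules to aggregated overlaps.

    presence(b)  <=>  range_fraction(b) >= range_threshold
                      OR max_dominion_fraction(b) >= dominion_threshold

    Species coded into zero biomes are excluded from the matrix and listed
    in ``PresenceMatrix.excluded`` with a logged warning.  A species is
    flagged a montane dweller if at least one of its presences disappears
    when montane dominions are ignored.
    """
    for name, thr in (("range", range_threshold), ("dominion", dominion_threshold)):
        if not (0.0 < thr <= 1.0):
            raise ValueError(f"{name} threshold must be in (0, 1], got {thr!r}")

    present = (aggregated.range_fraction >= range_threshold) | (
        aggregated.max_dominion_fraction >= dominion_threshold
    )
    present_non = (aggregated.range_fraction_nonmontane >= range_threshold) | (
        aggregated.max_dominion_fraction_nonmontane >= dominion_threshold
    )
    montane_dependent = present & ~present_non
    montane_flag = montane_dependent.any(axis=1)

    bsi = present.sum(axis=1)
    excluded = present.index[bsi == 0].tolist()
    if excluded:
        logger.warning(
            "%d species coded into zero biomes and excluded: %s",
            len(excluded), ", ".join(map(str, excluded)),
        )
    keep = present.index[bsi > 0]
    return PresenceMatrix(
        data=present.loc[keep],
        montane=montane_flag.loc[keep],
        excluded=excluded,
    )


def compute_bsi(matrix: PresenceMatrix) -> pd.DataFrame:
    """BSI per species (row sums) with specialization category.

    Returns a frame indexed by species with columns ``bsi`` (int) and
    ``category``.  Mean BSI equals the sum of the per-biome richness
    divided by the number of species.
    """
    if matrix.n_species == 0:
        raise ValueError("presence matrix is empty")
    bsi = matrix.data.sum(axis=1).astype(int)
    if (bsi == 0).any():
        bad = bsi.index[bsi == 0].tolist()
        raise ValueError(f"species with zero biomes (should be excluded): {bad}")
    cats = bsi.map(classify_specialization)
    return pd.DataFrame({"bsi": bsi, "category": cats})


def classify_specialization(bsi: int) -> str:
    """Map a BSI count to its specialization class.

    Boundaries: stenobiomic exactly at BSI = 1; semi-eurybiomic for
    1 < BSI < 5; extreme eurybiomic for BSI >= 5.
    """
    bsi = int(bsi)
    if bsi < 1 or bsi > len(BIOME_LABELS):
        raise ValueError(f"BSI must be in [1, {len(BIOME_LABELS)}], got {bsi}")
    if bsi == 1:
        return STENOBIOMIC
    if bsi < 5:
        return SEMI_EURYBIOMIC
    return EXTREME_EURYBIOMIC


def filter_montane(matrix: PresenceMatrix) -> PresenceMatrix:
    """Restrict the matrix to species NOT flagged as montane dwellers.

    This supports re-running the null analysis with mountain-range species
    removed, so that high-latitude biomes (notably the tundra) are not
    diluted by species reaching them only through altitudinal belts.
    """
    if matrix.montane is None:
        raise ValueError("presence matrix carries no montane flags")
    keep = matrix.montane.index[~matrix.montane.astype(bool)]
    if len(keep) == 0:
        logger.warning("all species are montane dwellers; filtered matrix is empty")
        return PresenceMatrix(
            data=matrix.data.iloc[0:0],
            clade=None if matrix.clade is None else matrix.clade.iloc[0:0],
            montane=matrix.montane.iloc[0:0],
        )
    return matrix.subset(keep)
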