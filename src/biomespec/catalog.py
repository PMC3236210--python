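"""Biome typology and the dominion -> biome catalog.

The analysis uses the ten Walter biome classes: evergreen tropical
rainforest (I), tropical deciduous woodland (II), savannah (II/III),
sub-tropical desert (III), sclerophyllous woodland (IV), temperate
evergreen forest (V), broad-leaf deciduous forest (VI), steppe/cold
desert (VII), taiga (VIII) and tundra (IX).  The savannah is a
first-class category of its own, not a union of II and III.

Species ranges are measured against *climatic dominions*, sub-biome
climatic regions.  Every dominion belongs to exactly one biome.
Montane dominions represent altitudinal vegetation belts and are
mapped to the biome whose habitat series they are analogous to
(e.g. alpine belts count toward the tundra).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

#: Canonical ordering of the ten Walter biome classes.
BIOME_LABELS: tuple[str, ...] = (
    "I", "II", "II/III", "III", "IV", "V", "VI", "VII", "VIII", "IX",
)

BIOME_NAMES: Mapping[str, str] = {
    "I": "evergreen tropical rainforest",
    "II": "tropical deciduous woodland",
    "II/III": "savannah",
    "III": "sub-tropical desert",
    "IV": "sclerophyllous woodland and shrubland",
    "V": "temperate evergreen forest",
    "VI": "broad-leaf deciduous forest",
    "VII": "steppe/cold desert",
    "VIII": "boreal coniferous forest (taiga)",
    "IX": "tundra",
}


class CatalogError(ValueError):
    """Raised for malformed catalogs or unknown dominion ids."""


@dataclass(frozen=True)
class Dominion:
    """A climatic dominion: the unit at which range overlap is measured.

    ``montane`` marks altitudinal-analog dominions; their ``biome`` is
    the analog biome they contribute to, not a montane category.
    """

    dominion_id: str
    biome: str
    montane: bool = False

    def __post_init__(self) -> None:
        if self.biome not in BIOME_LABELS:
            raise CatalogError(
                f"dominion {self.dominion_id!r}: unknown biome {self.biome!r}; "
                f"expected one of {', '.join(BIOME_LABELS)}"
            )


@dataclass
class BiomeCatalog:
    """Mapping from climatic dominions to the ten biome classes."""

    dominions: dict[str, Dominion] = field(default_factory=dict)

    @property
    def biomes(self) -> tuple[str, ...]:
        return BIOME_LABELS

    def add(self, dominion_id: str, biome: str, montane: bool = False) -> None:
        if dominion_id in self.dominions:
            raise CatalogError(f"duplicate dominion id {dominion_id!r}")
        self.dominions[dominion_id] = Dominion(dominion_id, biome, montane)

    def biome_of(self, dominion_id: str) -> str:
        try:
            return self.dominions[dominion_id].biome
        except KeyError:
            raise CatalogError(f"unknown dominion id {dominion_id!r}") from None

    def is_montane(self, dominion_id: str) -> bool:
        try:
            return self.dominions[dominion_id].montane
        except KeyError:
            raise CatalogError(f"unknown dominion id {dominion_id!r}") from None

    def dominions_of(self, biome: str, include_montane: bool = True) -> list[str]:
        return [
            d.dominion_id
            for d in self.dominions.values()
            if d.biome == biome and (include_montane or not d.montane)
        ]

    def validate(self, require_full_coverage: bool = False) -> None:
        """Check structural invariants.

        With ``require_full_coverage`` every biome must own at least one
        dominion (what a complete real-world catalog looks like).
        """
        if require_full_coverage:
            missing = [b for b in BIOME_LABELS if not self.dominions_of(b)]
            if missing:
                raise CatalogError(
                    f"biomes without any dominion: {', '.join(missing)}"
                )

    # -- serialization --------------------------------------------------

    @classmethod
    def from_dict(cls, payload: Mapping) -> "BiomeCatalog":
        cat = cls()
        for dom_id, rec in payload.get("dominions", {}).items():
            if isinstance(rec, str):
                cat.add(str(dom_id), rec)
            else:
                cat.add(
                    str(dom_id),
                    rec["biome"],
                    montane=bool(rec.get("montane", False)),
                )
        return cat

    def to_dict(self) -> dict:
        return {
            "biomes": list(BIOME_LABELS),
            "dominions": {
                d.dominion_id: {"biome": d.biome, "montane": d.montane}
                for d in self.dominions.values()
            },
        }

    @classmethod
    def read_yaml(cls, path: str | Path) -> "BiomeCatalog":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        if not isinstance(payload, dict):
            raise CatalogError(f"{path}: catalog file must be a mapping")
        return cls.from_dict(payload)

    def write_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_catalog(
    dominions_per_biome: int = 2,
    montane_biomes: Iterable[str] = ("VI", "VIII", "IX"),
) -> BiomeCatalog:
    """Build a generic catalog with ``dominions_per_biome`` plain dominions
    per biome plus one montane analog dominion for each biome in
    ``montane_biomes`` (cool-temperate belts by default, mirroring the way
    high-mountain vegetation series substitute for high-latitude biomes).
    """
    cat = BiomeCatalog()
    for biome in BIOME_LABELS:
        tag = biome.replace("/", "-")
        for k in range(1, dominions_per_biome + 1):
            cat.add(f"D{tag}.{k}", biome)
    for biome in montane_biomes:
        tag = biome.replace("/", "-")
        cat.add(f"M{tag}", biome, montane=True)
    return cat
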