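"""Synthetic species-by-biome datasets with controlled structure.

The generators emulate the statistical shape of a large herbivore
assemblage scored over the ten Walter biomes: fixed per-biome species
richness, a surplus of single-biome specialists relative to the random
null, an optional contingent of montane species, and trees produced by
the trait-dependent birth-death process.  The default preset is an
assemblage of 197 species with per-biome richness
(44, 93, 48, 35, 26, 44, 29, 45, 40, 10) and about 40% specialists.

Specialist excess is a mixture weight: with probability ``w`` a species
is assigned exactly one biome (chosen proportionally to the richness
marginals); otherwise its occupancies follow the independent null
process, conditioned on occupying at least one biome.  Column sums are
then repaired to match the target marginals exactly by moving single
presences between biomes, which preserves every species' BSI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import BIOME_LABELS, BiomeCatalog, default_catalog
from .coding import PresenceMatrix
from .nullmodel import RichnessMarginals, analytic_null_bsi
from .speciation import PhyloDataset, SpeciationModel, simulate_tree

#: per-biome richness of the default 197-species assemblage
DEFAULT_MARGINALS = (44, 93, 48, 35, 26, 44, 29, 45, 40, 10)
DEFAULT_N_SPECIES = 197
DEFAULT_SPECIALIST_FRACTION = 0.401


@dataclass
class SynthesisConfig:
    """Configuration of the presence-matrix generator."""

    n_species: int = DEFAULT_N_SPECIES
    marginals: tuple[int, ...] = DEFAULT_MARGINALS
    specialist_excess: Optional[float] = None   # None = calibrate to target
    target_specialist_fraction: float = DEFAULT_SPECIALIST_FRACTION
    montane_fraction: float = 0.0
    dominions_per_biome: int = 2
    clades: tuple[tuple[str, float], ...] = (("CladeA", 0.25), ("CladeB", 0.75))
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        if len(self.marginals) != len(BIOME_LABELS):
            raise ValueError("need one marginal per biome")
        for m in self.marginals:
            if not (0 <= m <= self.n_species):
                raise ValueError("marginals must lie in [0, n_species]")
        if sum(self.marginals) < self.n_species:
            raise ValueError(
                "marginals are infeasible: fewer total presences than species "
                "(every species needs at least one biome)"
            )
        for w in (self.specialist_excess, self.montane_fraction):
            if w is not None and not (0.0 <= w <= 1.0):
                raise ValueError("weights must lie in [0, 1]")

    @property
    def richness(self) -> RichnessMarginals:
        return RichnessMarginals(tuple(self.marginals), self.n_species)


def scaled_marginals(n_species: int,
                     base: tuple[int, ...] = DEFAULT_MARGINALS,
                     base_n: int = DEFAULT_N_SPECIES) -> tuple[int, ...]:
    """Rescale the reference richness marginals to another assemblage size,
    keeping at least one presence per species in total."""
    marg = [max(1, round(m * n_species / base_n)) for m in base]
    i = 0
    while sum(marg) < n_species:     # guarantee feasibility
        marg[i % len(marg)] += 1
        i += 1
    return tuple(min(m, n_species) for m in marg)


def calibrate_specialist_excess(
    marginals: RichnessMarginals, target_fraction: float
) -> float:
    """Mixture weight that yields the requested expected specialist share.

    The expected specialist fraction of the mixture is
    ``w + (1 - w) * p1`` with ``p1`` the null's conditional probability
    of BSI = 1, so ``w = (target - p1) / (1 - p1)`` (clipped to [0, 1]).
    """
    p1 = float(analytic_null_bsi(marginals)["bsi_pmf"][0])
    if p1 >= 1.0:
        return 0.0
    return float(np.clip((target_fraction - p1) / (1.0 - p1), 0.0, 1.0))


def _null_occupancy_row(p: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One species' occupancies under the null, conditioned on >= 1 biome."""
    for _ in range(200):
        row = rng.random(p.size) < p
        if row.any():
            return row
    row = np.zeros(p.size, dtype=bool)
    row[rng.choice(p.size, p=p / p.sum())] = True
    return row


def generate_presence_matrix(
    config: SynthesisConfig, seed: Optional[int] = None
) -> PresenceMatrix:
    """Sample a presence matrix with exact marginals and specialist excess.

    Every species occupies at least one biome and the column sums equal
    the configured marginals exactly.  Species are labeled ``sp0001``...
    and assigned clade labels by the configured proportions.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N, B = config.n_species, len(BIOME_LABELS)
    marg = np.asarray(config.marginals, dtype=int)
    p = marg / N
    w = config.specialist_excess
    if w is None:
        w = calibrate_specialist_excess(
            config.richness, config.target_specialist_fraction
        )

    occ = np.zeros((N, B), dtype=bool)
    p_norm = p / p.sum()
    for i in range(N):
        if rng.random() < w:
            occ[i, rng.choice(B, p=p_norm)] = True
        else:
            occ[i] = _null_occupancy_row(p, rng)

    _repair_marginals(occ, marg, rng)

    species = pd.Index([f"sp{i + 1:04d}" for i in range(N)], name="species")
    data = pd.DataFrame(occ, index=species, columns=list(BIOME_LABELS))
    clade_names = [c for c, _ in config.clades]
    clade_probs = np.array([q for _, q in config.clades], dtype=float)
    clade_probs /= clade_probs.sum()
    clades = pd.Series(
        rng.choice(clade_names, size=N, p=clade_probs), index=species,
        name="clade",
    )
    montane = pd.Series(
        rng.random(N) < config.montane_fraction, index=species, name="montane"
    )
    return PresenceMatrix(data=data, clade=clades, montane=montane)


def _repair_marginals(occ: np.ndarray, target: np.ndarray,
                      rng: np.random.Generator, max_iter: int = 100_000) -> None:
    """Move single presences from over-full to under-full biomes in place.

    Moving a presence (drop from biome b+, add to biome b-) keeps each
    species' BSI unchanged, so only the column structure is adjusted.
    """
    for _ in range(max_iter):
        cols = occ.sum(axis=0)
        diff = cols - target
        if not diff.any():
            return
        over = np.flatnonzero(diff > 0)
        under = np.flatnonzero(diff < 0)
        if over.size and under.size:
            # move one presence between biomes: BSI unchanged
            b_hi = int(rng.choice(over))
            b_lo = int(rng.choice(under))
            movable = np.flatnonzero(occ[:, b_hi] & ~occ[:, b_lo])
            if movable.size == 0:
                movable = np.flatnonzero(occ[:, b_hi])
                s = int(rng.choice(movable))
                occ[s, b_hi] = False       # rare: plain drop, then re-add below
                continue
            s = int(rng.choice(movable))
            occ[s, b_hi] = False
            occ[s, b_lo] = True
        elif over.size:
            # surplus presences: drop one from a generalist (keeps rows >= 1)
            b_hi = int(rng.choice(over))
            gen = np.flatnonzero(occ[:, b_hi] & (occ.sum(axis=1) >= 2))
            if gen.size == 0:
                raise RuntimeError("cannot drop presence without emptying a row")
            s = int(rng.choice(gen))
            occ[s, b_hi] = False
        else:
            # deficit: add a presence to a species not yet in the biome
            b_lo = int(rng.choice(under))
            addable = np.flatnonzero(~occ[:, b_lo])
            s = int(rng.choice(addable))
            occ[s, b_lo] = True
    raise RuntimeError("marginal repair did not converge")


def generate_overlap_table(
    matrix: PresenceMatrix,
    catalog: Optional[BiomeCatalog] = None,
    montane_fraction: float = 0.0,
    include_absences: bool = True,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, BiomeCatalog]:
    """Emit an overlap table whose coding reproduces ``matrix`` exactly.

    For each presence one coding rule is chosen at random: either the
    biome receives at least 15% of the species range (through a single
    dominion), or one dominion is covered to at least 50% while the
    range fraction stays below 15%.  Because at most six presences can
    carry a >= 15% range share within a unit budget, the range-rule is
    only used while budget remains.  Absences receive fractions strictly
    below both thresholds.  With ``montane_fraction`` > 0, qualifying
    presences are routed through montane analog dominions where the
    catalog provides them.
    """
    rng = np.random.default_rng(seed)
    if catalog is None:
        catalog = default_catalog()
    rows = []
    for species, presences in matrix.data.iterrows():
        budget = 1.0
        biomes = list(BIOME_LABELS)
        rng.shuffle(biomes)
        present = [b for b in biomes if presences[b]]
        absent = [b for b in biomes if not presences[b]]
        for biome in present:
            plain = catalog.dominions_of(biome, include_montane=False)
            montane = [
                d for d in catalog.dominions_of(biome) if catalog.is_montane(d)
            ]
            use_montane = montane and rng.random() < montane_fraction
            dominion = (
                montane[int(rng.integers(len(montane)))]
                if use_montane
                else plain[int(rng.integers(len(plain)))]
            )
            use_range_rule = budget >= 0.16 and rng.random() < 0.5
            if use_range_rule:
                rf = float(rng.uniform(0.15, min(0.25, budget)))
                df_ = float(rng.uniform(0.05, 0.49))
            else:
                rf = float(rng.uniform(0.01, min(0.14, budget)))
                df_ = float(rng.uniform(0.50, 0.95))
            budget -= rf
            rows.append((species, dominion, rf, df_))
        if include_absences:
            for biome in absent[: int(rng.integers(0, 3))]:
                plain = catalog.dominions_of(biome, include_montane=False)
                dominion = plain[int(rng.integers(len(plain)))]
                rf = float(rng.uniform(0.0, min(0.05, max(budget, 0.0))))
                if rf <= 0:
                    continue
                df_ = float(rng.uniform(0.0, 0.3))
                budget -= rf
                rows.append((species, dominion, rf, df_))
    table = pd.DataFrame(
        rows, columns=["species", "dominion", "range_fraction",
                       "dominion_fraction"],
    )
    return table, catalog


def generate_phylo_dataset(
    model: SpeciationModel,
    x0: float = 2.0,
    n_tips: Optional[int] = None,
    stop_time: Optional[float] = None,
    clamp: bool = False,
    round_traits: bool = False,
    seed: Optional[int] = None,
    max_tries: int = 20,
    dt: float = 0.05,
) -> PhyloDataset:
    """Simulate a tree + tip traits, retrying through complete extinctions.

    ``clamp`` restricts traits to the BSI range [1, 10]; ``round_traits``
    rounds them to integers (a realistic BSI is an integer count).
    """
    from .speciation import CompleteExtinctionError

    rng = np.random.default_rng(seed)
    last = None
    for _ in range(max_tries):
        sub = int(rng.integers(0, 2**31 - 1))
        try:
            ds = simulate_tree(model, x0=x0, n_tips=n_tips,
                               stop_time=stop_time, dt=dt, seed=sub)
        except CompleteExtinctionError as err:
            last = err
            continue
        traits = ds.traits
        if clamp:
            traits = traits.clip(1.0, 10.0)
        if round_traits:
            traits = traits.round()
        return PhyloDataset(tree=ds.tree, traits=traits)
    raise RuntimeError(
        f"all {max_tries} simulation attempts went extinct: {last}"
    )
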