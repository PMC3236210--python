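import dendropy
import numpy as np
import pandas as pd
import pytest

from biomespec import (
    BiomeCatalog,
    PresenceMatrix,
    RichnessMarginals,
    SpeciationModel,
    generate_phylo_dataset,
)
from biomespec.catalog import BIOME_LABELS

#: per-biome richness of the 197-species reference assemblage
RUMINANT_MARGINALS = (44, 93, 48, 35, 26, 44, 29, 45, 40, 10)
CERVID_MARGINALS = (15, 25, 7, 2, 5, 18, 11, 10, 12, 1)
BOVID_MARGINALS = (25, 65, 38, 32, 21, 25, 13, 29, 23, 9)


@pytest.fixture(scope="session")
def ruminant_marginals() -> RichnessMarginals:
    return RichnessMarginals(RUMINANT_MARGINALS, 197)


@pytest.fixture()
def toy_catalog() -> BiomeCatalog:
    cat = BiomeCatalog()
    cat.add("d2a", "II")
    cat.add("d2b", "II")
    cat.add("d3", "III")
    cat.add("d9", "IX")
    cat.add("m9", "IX", montane=True)
    return cat


def make_presence(rows: dict[str, list[str]], montane: dict[str, bool] | None = None,
                  clade: dict[str, str] | None = None) -> PresenceMatrix:
    """Build a presence matrix from {species: [biomes]} shorthand."""
    species = list(rows)
    data = pd.DataFrame(False, index=pd.Index(species, name="species"),
                        columns=list(BIOME_LABELS))
    for sp, biomes in rows.items():
        for b in biomes:
            data.loc[sp, b] = True
    kw = {}
    if montane is not None:
        kw["montane"] = pd.Series(montane)
    if clade is not None:
        kw["clade"] = pd.Series(clade)
    return PresenceMatrix(data=data, **kw)


@pytest.fixture(scope="session")
def small_constant_dataset():
    """A ~20-tip tree simulated under trait-independent rates."""
    model = SpeciationModel(shape="constant", lambda0=0.15, mu=0.03,
                            sigma2=0.05)
    return model, generate_phylo_dataset(model, x0=3.0, n_tips=20, seed=42)


@pytest.fixture()
def polytomy_tree() -> dendropy.Tree:
    return dendropy.Tree.get(
        data="((a:1,b:1,c:1,d:1):2,(e:1.5,f:1.5):1.5);", schema="newick"
    )


def assert_binary(tree: dendropy.Tree) -> None:
    for node in tree.preorder_node_iter():
        assert len(node.child_nodes()) in (0, 2)


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    return {l.taxon.label: l.distance_from_root() for l in tree.leaf_node_iter()}
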