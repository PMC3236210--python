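"""Trait-dependent birth-death models and their forward simulator.

The speciation rate is a function lambda(x) of a continuous trait x
(here the biomic specialization index), the extinction rate mu is
constant, and the trait evolves by Brownian motion with diffusion rate
sigma2 (trait^2 per Myr) and optional directional drift phi (trait per
Myr; positive phi pushes lineages toward higher trait values, i.e.
toward generalism).

Four speciation shapes are supported:

=========  =============================================================
constant   lambda(x) = lambda0
linear     lambda(x) = max(0, lambda0 + slope * x)   (clamped at zero)
sigmoid    lambda(x) = lambda1 + (lambda0 - lambda1) /
                       (1 + exp(steepness * (x - xmid)))
modal      lambda(x) = lambda1 + (lambda0 - lambda1) *
                       exp(-(x - xmid)^2 / (2 * width^2))
=========  =============================================================

With the decreasing sigmoid, ``lambda0`` is the rate plateau at low
trait values (specialists) and ``lambda1`` the plateau at high values
(generalists); ``xmid`` is the inflection point.  Free-parameter counts
(including mu and sigma2) are 3 / 4 / 6 / 6, plus one for drift.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

SHAPES = ("constant", "linear", "sigmoid", "modal")

#: free parameters per shape, in fitting order (drift appended when used)
SHAPE_PARAMS: dict[str, tuple[str, ...]] = {
    "constant": ("lambda0", "mu", "sigma2"),
    "linear": ("lambda0", "slope", "mu", "sigma2"),
    "sigmoid": ("lambda0", "lambda1", "xmid", "steepness", "mu", "sigma2"),
    "modal": ("lambda0", "lambda1", "xmid", "width", "mu", "sigma2"),
}


class CompleteExtinctionError(RuntimeError):
    """The simulated clade died out before reaching the stop condition."""


@dataclass(frozen=True)
class SpeciationModel:
    """Parameterization of lambda(x), mu, sigma2 and optional drift."""

    shape: str
    lambda0: float
    mu: float = 0.0
    sigma2: float = 0.0
    lambda1: Optional[float] = None
    xmid: Optional[float] = None
    steepness: Optional[float] = None
    width: Optional[float] = None
    slope: Optional[float] = None
    drift: float = 0.0
    with_drift: bool = False

    def __post_init__(self) -> None:
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected {SHAPES}")
        for name in ("lambda0", "mu", "sigma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        required = {
            "constant": (),
            "linear": ("slope",),
            "sigmoid": ("lambda1", "xmid", "steepness"),
            "modal": ("lambda1", "xmid", "width"),
        }[self.shape]
        for name in required:
            if getattr(self, name) is None:
                raise ValueError(f"shape {self.shape!r} requires {name}")
        if self.lambda1 is not None and self.lambda1 < 0:
            raise ValueError("lambda1 must be >= 0")
        if self.width is not None and self.width <= 0:
            raise ValueError("width must be > 0")
        if self.steepness is not None and self.steepness <= 0:
            raise ValueError("steepness must be > 0")

    @property
    def n_params(self) -> int:
        return len(SHAPE_PARAMS[self.shape]) + (1 if self.with_drift else 0)

    def lambda_at(self, x):
        """Speciation rate at trait value(s) ``x`` (total, continuous)."""
        x = np.asarray(x, dtype=float)
        if self.shape == "constant":
            out = np.full_like(x, self.lambda0)
        elif self.shape == "linear":
            out = np.maximum(0.0, self.lambda0 + self.slope * x)
        elif self.shape == "sigmoid":
            z = np.clip(self.steepness * (x - self.xmid), -700, 700)
            out = self.lambda1 + (self.lambda0 - self.lambda1) / (1.0 + np.exp(z))
        else:  # modal
            out = self.lambda1 + (self.lambda0 - self.lambda1) * np.exp(
                -((x - self.xmid) ** 2) / (2.0 * self.width**2)
            )
        return out if out.ndim else float(out)


def lambda_at(model: SpeciationModel, x):
    """Functional alias for :meth:`SpeciationModel.lambda_at`."""
    return model.lambda_at(x)


@dataclass
class PhyloDataset:
    """A binary (or to-be-resolved) tree plus tip trait values.

    ``traits`` is indexed by tip label and must cover the tip set exactly.
    """

    tree: dendropy.Tree
    traits: pd.Series

    def __post_init__(self) -> None:
        tips = {leaf.taxon.label for leaf in self.tree.leaf_node_iter()}
        have = set(self.traits.index)
        if tips != have:
            missing = sorted(tips - have)
            extra = sorted(have - tips)
            parts = []
            if missing:
                parts.append(f"tips without trait values: {missing}")
            if extra:
                parts.append(f"trait rows without tips: {extra}")
            raise ValueError("; ".join(parts))
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length in tree")

    @property
    def n_tips(self) -> int:
        return len(self.traits)

    def is_binary(self) -> bool:
        for node in self.tree.preorder_node_iter():
            n = len(node.child_nodes())
            if n not in (0, 2):
                return False
        return True


# ---------------------------------------------------------------------------
# forward simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    model: SpeciationModel,
    x0: float,
    stop_time: Optional[float] = None,
    n_tips: Optional[int] = None,
    dt: float = 0.05,
    seed: Optional[int] = None,
    prune_extinct: bool = True,
    max_lineages: int = 100_000,
) -> PhyloDataset:
    """Simulate a trait-dependent birth-death tree from a single lineage.

    Time advances in steps of ``dt`` Myr.  Per step each lineage
    speciates with probability lambda(x) * dt, goes extinct with
    probability mu * dt, and its trait takes a Brownian increment
    ``phi * dt + sqrt(sigma2 * dt) * z``.  Exactly one of ``stop_time``
    (total duration) or ``n_tips`` (extant lineage count) must be given;
    with ``n_tips`` the clock stops at the end of the step in which the
    count is reached.

    Raises :class:`CompleteExtinctionError` when every lineage dies
    before the stop condition; the caller may retry with a new seed.
    """
    if (stop_time is None) == (n_tips is None):
        raise ValueError("give exactly one of stop_time or n_tips")
    if stop_time is not None and stop_time <= 0:
        raise ValueError("stop_time must be positive")
    if n_tips is not None and n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    if model.lambda_at(x0) <= 0 and (n_tips is not None and n_tips > 1):
        raise ValueError("lambda(x0) must be positive to grow the tree")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)

    # flat node table
    parent: list[int] = [-1]
    t_birth: list[float] = [0.0]
    t_end: list[float] = [np.nan]
    alive_ids = np.array([0], dtype=int)
    traits = np.array([float(x0)])
    died: set[int] = set()

    sd_step = float(np.sqrt(model.sigma2 * dt))
    drift_step = model.drift * dt
    t = 0.0
    while True:
        if stop_time is not None and t >= stop_time - 1e-12:
            break
        if n_tips is not None and alive_ids.size >= n_tips:
            break
        if alive_ids.size == 0:
            raise CompleteExtinctionError(
                f"clade extinct at t={t:.3f} before stop condition"
            )
        if alive_ids.size > max_lineages:
            raise RuntimeError("lineage count exceeded max_lineages")
        step = dt
        if stop_time is not None:
            step = min(dt, stop_time - t)
        lam = np.asarray(model.lambda_at(traits), dtype=float)
        u = rng.random(alive_ids.size)
        p_spec = lam * step
        p_dead = model.mu * step
        speciate = u < p_spec
        die = (~speciate) & (u < p_spec + p_dead)
        t_next = t + step

        next_ids = []
        next_traits = []
        for i, nid in enumerate(alive_ids):
            if speciate[i]:
                t_end[nid] = t_next
                for _ in range(2):
                    parent.append(nid)
                    t_birth.append(t_next)
                    t_end.append(np.nan)
                    next_ids.append(len(parent) - 1)
                    next_traits.append(traits[i])
            elif die[i]:
                t_end[nid] = t_next
                died.add(nid)
            else:
                next_ids.append(nid)
                next_traits.append(traits[i])
        alive_ids = np.array(next_ids, dtype=int)
        traits = np.array(next_traits, dtype=float)
        if traits.size and (sd_step > 0 or drift_step != 0):
            traits = traits + drift_step + sd_step * rng.standard_normal(traits.size)
        t = t_next

    if alive_ids.size == 0:
        raise CompleteExtinctionError("clade extinct at stop time")
    for i, nid in enumerate(alive_ids):
        t_end[nid] = t

    return _build_dataset(
        parent, t_birth, t_end, alive_ids, traits, prune_extinct=prune_extinct
    )


def _build_dataset(parent, t_birth, t_end, alive_ids, alive_traits,
                   prune_extinct=True) -> PhyloDataset:
    n = len(parent)
    children: list[list[int]] = [[] for _ in range(n)]
    for nid in range(1, n):
        children[parent[nid]].append(nid)

    alive = np.zeros(n, dtype=bool)
    alive[alive_ids] = True
    keep = alive.copy()
    if prune_extinct:
        # mark ancestors of extant tips
        for nid in alive_ids:
            p = parent[nid]
            while p >= 0 and not keep[p]:
                keep[p] = True
                p = parent[p]
    else:
        keep[:] = True

    trait_of = {int(nid): float(x) for nid, x in zip(alive_ids, alive_traits)}
    labels: dict[int, str] = {}
    counter = [0]

    def newick(nid: int) -> str:
        kids = [k for k in children[nid] if keep[k]]
        length = t_end[nid] - t_birth[nid]
        # suppress unifurcations left by pruning
        while len(kids) == 1:
            child = kids[0]
            length += t_end[child] - t_birth[child]
            nid = child
            kids = [k for k in children[nid] if keep[k]]
        if not kids:
            counter[0] += 1
            lab = f"s{counter[0]}"
            labels[nid] = lab
            return f"{lab}:{length:.10g}"
        inner = ",".join(newick(k) for k in kids)
        return f"({inner}):{length:.10g}"

    nwk = newick(0) + ";"
    tree = dendropy.Tree.get(data=nwk, schema="newick")
    traits = pd.Series(
        {labels[nid]: trait_of.get(nid, np.nan) for nid in labels},
        name="trait",
    )
    # with prune_extinct, every retained tip is extant and carries a trait;
    # otherwise extinct tips remain in the tree with NaN traits
    tip_labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    traits = traits.reindex(tip_labels)
    return PhyloDataset(tree=tree, traits=traits)
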