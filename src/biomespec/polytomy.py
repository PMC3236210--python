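"""Random resolution of polytomies into distributions of binary trees.

The likelihood machinery requires strictly bifurcating trees, while
supertrees typically contain polytomies.  Each polytomy is resolved by
sequential random pairing: two of the node's children are drawn
uniformly, detached, and re-attached under a new internal node, until
only two children remain.  The new internal branch receives a length
drawn uniformly on (0, eps_max * min(child branch lengths)], and the
same amount is removed from both grouped children, so every
root-to-tip path length is conserved exactly.

This is a simple uninformed randomization; it explores resolution
uncertainty without any attempt at branch-length inference.
"""

from __future__ import annotations

from typing import Optional

import dendropy
import numpy as np


def is_binary(tree: dendropy.Tree) -> bool:
    return all(
        len(n.child_nodes()) in (0, 2) for n in tree.preorder_node_iter()
    )


def _resolve_once(tree: dendropy.Tree, rng: np.random.Generator,
                  eps_max: float) -> dendropy.Tree:
    for node in list(tree.preorder_node_iter()):
        children = list(node.child_nodes())
        while len(children) > 2:
            i, j = rng.choice(len(children), size=2, replace=False)
            a, b = children[int(i)], children[int(j)]
            len_a = a.edge.length or 0.0
            len_b = b.edge.length or 0.0
            # u in (0, 1]: keep the new branch strictly positive when possible
            u = 1.0 - rng.random()
            delta = u * eps_max * min(len_a, len_b)
            node.remove_child(a)
            node.remove_child(b)
            new = node.new_child(edge_length=delta)
            new.add_child(a)
            new.add_child(b)
            a.edge.length = len_a - delta
            b.edge.length = len_b - delta
            children = [c for c in children if c is not a and c is not b]
            children.append(new)
    return tree


def resolve_polytomies(
    tree: dendropy.Tree,
    n_resolutions: int = 100,
    seed: Optional[int] = None,
    eps_max: float = 0.5,
) -> list[dendropy.Tree]:
    """Produce ``n_resolutions`` independently resolved binary trees.

    An already-binary tree is returned unchanged (as copies).  ``eps_max``
    bounds each new internal branch to that fraction of the shorter of
    the two grouped child branches.
    """
    if n_resolutions < 1:
        raise ValueError("n_resolutions must be >= 1")
    if not (0 < eps_max <= 1):
        raise ValueError("eps_max must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_resolutions):
        copy = tree.clone(depth=1)
        if not is_binary(copy):
            _resolve_once(copy, rng, eps_max)
        out.append(copy)
    return out
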