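"""Independent brute-force oracle for Wagner parsimony on small trees.

Everything here is deliberately separate from the package's dynamic
programme: costs are computed by exhaustive enumeration over all internal
node assignments, so agreement between the two routes is meaningful.
"""

from __future__ import annotations

import itertools

import numpy as np

from stkflux.io import SpeciesTree


def enumerate_shapes(n_leaves: int):
    """All rooted multifurcating tree shapes with exactly ``n_leaves`` leaves.

    A shape is "L" for a leaf, or a sorted tuple of child shapes (>= 2
    children).  Counts: 1, 1, 2, 5, 12, 33 for n = 1..6.
    """
    if n_leaves == 1:
        return ["L"]
    shapes = set()
    for parts in _partitions(n_leaves, n_leaves):
        if len(parts) < 2:
            continue
        child_choices = [enumerate_shapes(p) for p in parts]
        for combo in itertools.product(*child_choices):
            shapes.add(tuple(sorted(combo, key=repr)))
    return sorted(shapes, key=repr)


def _partitions(n: int, max_part: int):
    """Non-increasing integer partitions of n."""
    if n == 0:
        yield ()
        return
    for first in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def shape_to_newick(shape) -> str:
    counter = itertools.count()

    def build(node) -> str:
        if node == "L":
            return f"L{next(counter)}"
        return "(" + ",".join(build(c) for c in node) + ")"

    return build(shape) + ";"


def step_cost_matrix(n_states: int, gain: float, loss: float) -> np.ndarray:
    s = np.arange(n_states)
    diff = s[None, :] - s[:, None]
    return np.where(diff > 0, gain * diff, -loss * diff).astype(float)


def brute_min_costs(
    tree: SpeciesTree,
    leaf_profiles: np.ndarray,  # (n_profiles, n_leaves), leaf order = tree.leaves
    gain: float,
    loss: float,
    cap: int,
) -> np.ndarray:
    """Exhaustive minimum cost per profile over all internal assignments."""
    step = step_cost_matrix(cap + 1, gain, loss)
    internal = [n for n in tree.postorder if tree.children[n]]
    idx_internal = {n: i for i, n in enumerate(internal)}
    idx_leaf = {n: i for i, n in enumerate(tree.leaves)}
    assigns = np.array(
        list(itertools.product(range(cap + 1), repeat=len(internal))), dtype=int
    )  # (A, m)
    n_profiles = leaf_profiles.shape[0]
    total = np.zeros((assigns.shape[0], n_profiles))
    for parent, child in tree.branches:
        p_states = assigns[:, idx_internal[parent]]
        if child in idx_internal:
            c_states = assigns[:, idx_internal[child]]
            total += step[p_states, c_states][:, None]
        else:
            c_states = leaf_profiles[:, idx_leaf[child]]
            total += step[p_states[:, None], c_states[None, :]]
    return total.min(axis=0)


def fitch_changes(tree: SpeciesTree, leaf_states: dict[str, int]) -> int:
    """Fitch parsimony change count for one binary character (binary tree)."""
    changes = 0
    sets: dict[str, set[int]] = {}
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            sets[node] = {leaf_states[node]}
            continue
        inter = set.intersection(*(sets[k] for k in kids))
        if inter:
            sets[node] = inter
        else:
            sets[node] = set.union(*(sets[k] for k in kids))
            changes += 1
    return changes
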