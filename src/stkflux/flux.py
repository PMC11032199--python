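"""Ancestral gene-content reconstruction by asymmetric Wagner parsimony.

Given a family-by-taxon count matrix (a phyletic profile) and a rooted
species tree, each family's counts are propagated to ancestral nodes by
minimising the total cost of unit changes along branches, where a unit gain
(+1) costs ``gain_penalty`` and a unit loss (-1) costs ``loss_penalty``.  A
gain penalty of 2 (the default) makes the reconstruction conservative about
inventing genes: a family has to be independently absent from enough lineages
before parallel losses become cheaper than a late gain.

The minimisation is an exact Sankoff-style dynamic programme over integer
states 0..cap, vectorised across families.  Ties are broken deterministically
toward the smaller count, biasing against inflated ancestral genomes.

Per branch, a family is *gained* when the parent count is 0 and the child
count positive, and *lost* when the parent count is positive and the child
count 0; ``units_gained``/``units_lost`` additionally count every +1/-1 step,
so multi-copy expansions and contractions are visible either way.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SpeciesTree

__all__ = [
    "PhyleticProfile",
    "FluxConfig",
    "BranchFlux",
    "FluxResult",
    "FluxSummary",
    "wagner_reconstruct",
    "summarize_flux",
]

_INF = np.inf


@dataclasses.dataclass(frozen=True)
class PhyleticProfile:
    families: tuple[str, ...]
    taxa: tuple[str, ...]
    counts: np.ndarray  # (n_families, n_taxa), non-negative ints

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.families), len(self.taxa)):
            raise ValueError("counts shape does not match families x taxa")
        if (counts < 0).any():
            raise ValueError("negative counts")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PhyleticProfile":
        return cls(
            families=tuple(str(i) for i in df.index),
            taxa=tuple(str(c) for c in df.columns),
            counts=df.to_numpy(dtype=np.int64),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.families),
                            columns=list(self.taxa))


@dataclasses.dataclass(frozen=True)
class FluxConfig:
    gain_penalty: float = 2.0
    loss_penalty: float = 1.0
    max_count_cap: int | None = None  # default: max observed count

    def __post_init__(self) -> None:
        if self.gain_penalty <= 0 or self.loss_penalty <= 0:
            raise ValueError("penalties must be positive")


@dataclasses.dataclass
class BranchFlux:
    families_gained: set[str]
    families_lost: set[str]
    units_gained: int
    units_lost: int


@dataclasses.dataclass
class FluxResult:
    families: tuple[str, ...]
    node_ids: tuple[str, ...]
    ancestral_counts: dict[str, np.ndarray]  # node id -> (n_families,) counts
    per_branch: dict[tuple[str, str], BranchFlux]
    total_cost: float
    dropped_families: tuple[str, ...] = ()


@dataclasses.dataclass
class FluxSummary:
    per_branch: pd.DataFrame  # parent, child, gained, lost, units_gained, units_lost
    per_node: pd.DataFrame  # node, families_present
    category_crosstab: pd.DataFrame | None = None


def _step_cost_matrix(n_states: int, gain: float, loss: float) -> np.ndarray:
    s = np.arange(n_states)
    diff = s[None, :] - s[:, None]  # child - parent
    return np.where(diff > 0, gain * diff, -loss * diff).astype(float)


def wagner_reconstruct(
    profile: PhyleticProfile,
    tree: SpeciesTree,
    cfg: FluxConfig = FluxConfig(),
) -> FluxResult:
    """Minimum-cost integer ancestral counts for every family.

    Families absent from every leaf carry no information and are dropped with
    a warning.  Counts above ``cfg.max_count_cap`` (when set) are capped
    before reconstruction.
    """
    missing = set(profile.taxa) - set(tree.leaves)
    if missing:
        raise ValueError(f"profile taxa absent from tree: {sorted(missing)}")

    counts = np.asarray(profile.counts, dtype=np.int64)
    if cfg.max_count_cap is not None:
        counts = np.minimum(counts, cfg.max_count_cap)
    keep = counts.sum(axis=1) > 0
    dropped = tuple(f for f, k in zip(profile.families, keep) if not k)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} families absent from all leaves"
        )
    families = tuple(f for f, k in zip(profile.families, keep) if k)
    counts = counts[keep]
    n_fam = len(families)
    cap = int(counts.max()) if n_fam else 1
    n_states = cap + 1
    step = _step_cost_matrix(n_states, cfg.gain_penalty, cfg.loss_penalty)

    taxon_col = {t: j for j, t in enumerate(profile.taxa)}

    # bottom-up: C[node][f, s] = min cost of the subtree at node given state s
    cost: dict[str, np.ndarray] = {}
    for node in tree.postorder:
        kids = tree.children[node]
        if not kids:
            leaf_counts = counts[:, taxon_col[node]]
            c = np.full((n_fam, n_states), _INF)
            c[np.arange(n_fam), leaf_counts] = 0.0
        else:
            c = np.zeros((n_fam, n_states))
            for kid in kids:
                # min over child state t of C[kid][f,t] + step[s,t]
                c += (cost[kid][:, None, :] + step[None, :, :]).min(axis=2)
        cost[node] = c

    # top-down backtrace; argmin returns the first (= smallest-count) optimum
    assignment: dict[str, np.ndarray] = {}
    root = tree.root_id
    assignment[root] = np.argmin(cost[root], axis=1) if n_fam else np.zeros(0, int)
    total_cost = float(cost[root].min(axis=1).sum()) if n_fam else 0.0
    for node in tree.preorder:
        if node == root:
            continue
        parent_states = assignment[tree.parent[node]]
        cand = cost[node] + step[parent_states, :]  # (n_fam, n_states)
        assignment[node] = np.argmin(cand, axis=1)

    per_branch: dict[tuple[str, str], BranchFlux] = {}
    fam_arr = np.array(families)
    for parent, child in tree.branches:
        p = assignment[parent]
        c = assignment[child]
        diff = c - p
        gained_mask = (p == 0) & (c > 0)
        lost_mask = (p > 0) & (c == 0)
        per_branch[(parent, child)] = BranchFlux(
            families_gained=set(fam_arr[gained_mask]),
            families_lost=set(fam_arr[lost_mask]),
            units_gained=int(diff[diff > 0].sum()),
            units_lost=int(-diff[diff < 0].sum()),
        )

    return FluxResult(
        families=families,
        node_ids=tuple(tree.preorder),
        ancestral_counts={n: assignment[n].copy() for n in tree.preorder},
        per_branch=per_branch,
        total_cost=total_cost,
        dropped_families=dropped,
    )


def summarize_flux(
    result: FluxResult,
    tree: SpeciesTree,
    family_categories: Mapping[str, str] | None = None,
) -> FluxSummary:
    """Per-branch gain/loss tallies and per-node family totals.

    With ``family_categories`` (family id -> COG category letter), a
    branch x category cross-tabulation of gained/lost family counts is added.
    """
    rows = []
    for (parent, child), bf in result.per_branch.items():
        rows.append(
            {
                "parent": parent,
                "child": child,
                "gained": len(bf.families_gained),
                "lost": len(bf.families_lost),
                "units_gained": bf.units_gained,
                "units_lost": bf.units_lost,
            }
        )
    per_branch = pd.DataFrame(
        rows, columns=["parent", "child", "gained", "lost",
                       "units_gained", "units_lost"]
    )
    node_rows = [
        {"node": n, "families_present": int((result.ancestral_counts[n] > 0).sum())}
        for n in result.node_ids
    ]
    per_node = pd.DataFrame(node_rows, columns=["node", "families_present"])

    crosstab = None
    if family_categories is not None:
        cat_rows = []
        for (parent, child), bf in result.per_branch.items():
            for fam in bf.families_gained:
                cat_rows.append(
                    {"child": child, "event": "gain",
                     "category": family_categories.get(fam, "none")}
                )
            for fam in bf.families_lost:
                cat_rows.append(
                    {"child": child, "event": "loss",
                     "category": family_categories.get(fam, "none")}
                )
        if cat_rows:
            df = pd.DataFrame(cat_rows)
            crosstab = (
                df.groupby(["child", "event", "category"])
                .size()
                .unstack(fill_value=0)
            )
        else:
            crosstab = pd.DataFrame()
    return FluxSummary(per_branch=per_branch, per_node=per_node,
                       category_crosstab=crosstab)
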