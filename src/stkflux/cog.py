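"""Region-based COG functional-category assignment from tabular homology hits.

A protein is scanned against the COG database (BLAST, e <= 1e-5) and its hits
are merged into regions by single-linkage interval overlap.  A region is
assigned a one-letter COG category when at least ``min_hits`` hits carry that
category and no more than ``max_conflict`` of the region is classified to
another category.  Regions that fail get a marker instead:

    ``-``  no hits at all
    ``?``  two or more categories compete over the same region
    ``+``  best-supported category has fewer than ``min_hits`` hits

Hits carrying multi-letter categories (e.g. "KT") support each letter.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

__all__ = [
    "CogHit",
    "Region",
    "RegionCall",
    "CallConfig",
    "build_regions",
    "call_region",
    "call_protein",
    "protein_category_profile",
    "family_category",
]

MARKERS = ("-", "?", "+")


@dataclasses.dataclass(frozen=True)
class CogHit:
    """One homology hit; coordinates 1-based inclusive on the query."""

    query_id: str
    q_start: int
    q_end: int
    cog_id: str
    category: str  # one or more one-letter categories
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"{self.query_id}: q_start > q_end")
        if not self.category:
            raise ValueError(f"{self.query_id}: empty category")


@dataclasses.dataclass(frozen=True)
class Region:
    r_start: int
    r_end: int
    hits: tuple[CogHit, ...]  # empty for no-hit gap regions


@dataclasses.dataclass(frozen=True)
class RegionCall:
    query_id: str
    r_start: int
    r_end: int
    verdict: str  # category letter or one of MARKERS
    supporting_hits: int
    conflicting_fraction: float


@dataclasses.dataclass(frozen=True)
class CallConfig:
    min_hits: int = 5
    max_conflict: float = 0.5
    # "coverage": conflict = fraction of region residues covered by hits of
    # another category.  "hits": conflict = fraction of the region's hits
    # carrying another category.
    conflict_mode: str = "coverage"


def build_regions(hits: Sequence[CogHit], protein_length: int) -> list[Region]:
    """Tile [1, protein_length] into hit regions and no-hit gap regions.

    Hit regions are the connected components of hits under interval overlap
    of >= 1 residue (single-linkage merge); remaining residues form ``-``
    regions.  Regions never overlap and jointly cover the protein.
    """
    for h in hits:
        if h.q_end > protein_length or h.q_start < 1:
            raise ValueError(
                f"{h.query_id}: hit [{h.q_start},{h.q_end}] outside protein "
                f"of length {protein_length}"
            )
    regions: list[Region] = []
    pos = 1
    for comp_start, comp_end, comp_hits in _merge_components(hits):
        if comp_start > pos:
            regions.append(Region(pos, comp_start - 1, ()))
        regions.append(Region(comp_start, comp_end, comp_hits))
        pos = comp_end + 1
    if pos <= protein_length:
        regions.append(Region(pos, protein_length, ()))
    return regions


def _merge_components(
    hits: Sequence[CogHit],
) -> list[tuple[int, int, tuple[CogHit, ...]]]:
    ordered = sorted(hits, key=lambda h: (h.q_start, h.q_end, h.cog_id))
    comps: list[tuple[int, int, tuple[CogHit, ...]]] = []
    cur: list[CogHit] = []
    cur_start = cur_end = 0
    for h in ordered:
        if cur and h.q_start <= cur_end:  # >= 1 shared residue
            cur.append(h)
            cur_end = max(cur_end, h.q_end)
        else:
            if cur:
                comps.append((cur_start, cur_end, tuple(cur)))
            cur = [h]
            cur_start, cur_end = h.q_start, h.q_end
    if cur:
        comps.append((cur_start, cur_end, tuple(cur)))
    return comps


def _coverage_fraction(
    region: Region, hits: Iterable[CogHit]
) -> float:
    """Fraction of region residues covered by the given hits."""
    length = region.r_end - region.r_start + 1
    spans = sorted(
        (max(h.q_start, region.r_start), min(h.q_end, region.r_end)) for h in hits
    )
    covered = 0
    cur_s = cur_e = None
    for s, e in spans:
        if e < s:
            continue
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        covered += cur_e - cur_s + 1
    return covered / length


def call_region(region: Region, cfg: CallConfig = CallConfig()) -> RegionCall:
    """Apply the >=min_hits / <=max_conflict rule to one region."""
    qid = region.hits[0].query_id if region.hits else ""
    if not region.hits:
        return RegionCall(qid, region.r_start, region.r_end, "-", 0, 0.0)

    support: dict[str, int] = {}
    for h in region.hits:
        for letter in set(h.category):
            support[letter] = support.get(letter, 0) + 1

    def conflict(letter: str) -> float:
        others = [h for h in region.hits if letter not in h.category]
        if cfg.conflict_mode == "hits":
            return len(others) / len(region.hits)
        return _coverage_fraction(region, others)

    best_support = max(support.values())
    if best_support < cfg.min_hits:
        return RegionCall(qid, region.r_start, region.r_end, "+", best_support, 0.0)

    qualifying = sorted(
        letter
        for letter, n in support.items()
        if n >= cfg.min_hits and conflict(letter) <= cfg.max_conflict
    )
    if len(qualifying) == 1:
        letter = qualifying[0]
        return RegionCall(
            qid, region.r_start, region.r_end, letter, support[letter], conflict(letter)
        )
    # Either several categories qualify over the same residues, or every
    # well-supported category is drowned by >max_conflict of another one.
    return RegionCall(qid, region.r_start, region.r_end, "?", best_support, 1.0)


def call_protein(
    hits: Sequence[CogHit], protein_length: int, cfg: CallConfig = CallConfig()
) -> list[RegionCall]:
    regions = build_regions(hits, protein_length)
    calls = []
    for region in regions:
        call = call_region(region, cfg)
        if not region.hits:
            call = dataclasses.replace(call, query_id=hits[0].query_id if hits else "")
        calls.append(call)
    return calls


def protein_category_profile(calls: Sequence[RegionCall]) -> tuple[str, str]:
    """Ordered verdict string plus the dominant per-protein category.

    The dominant category is the category of the longest category-assigned
    region ("none" when no region got a category; ties broken toward the
    earlier region).
    """
    profile = "".join(c.verdict for c in calls)
    best_len = 0
    dominant = "none"
    for c in calls:
        if c.verdict in MARKERS:
            continue
        length = c.r_end - c.r_start + 1
        if length > best_len:
            best_len = length
            dominant = c.verdict
    return profile, dominant


def family_category(dominant_categories: Sequence[str]) -> str:
    """Modal dominant category across a family's member proteins; ties -> "?"."""
    counts: dict[str, int] = {}
    for cat in dominant_categories:
        if cat == "none":
            continue
        counts[cat] = counts.get(cat, 0) + 1
    if not counts:
        return "none"
    top = max(counts.values())
    winners = [c for c, n in counts.items() if n == top]
    return winners[0] if len(winners) == 1 else "?"
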