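"""Domain architectures, membrane sidedness, and tandem-array statistics.

A protein's architecture is the ordered string of its domain tokens (grouped
by domain family, e.g. several TPR accessions collapse to "TPR") interleaved
with transmembrane helices ("TM") and an optional signal peptide ("SP").
Under the single-membrane convention used for these bacteria, topological
"inside" segments are cytoplasmic and "outside" segments periplasmic; a
domain's side is the side of the segment containing its midpoint.

When a topology gives only TM helices, sides are inferred by parity: the
N-terminus is cytoplasmic unless a signal peptide is present (then the mature
chain starts periplasmic), and the side flips at every TM helix.

Tandem arrays are maximal runs of consecutive tokens of one domain group;
TM and SP tokens do not interrupt a run, since a repeat region flanking a
membrane helix is still one contiguous array at the sequence level.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import Segment

__all__ = [
    "DomainHit",
    "Token",
    "ProteinArchitecture",
    "resolve_domain_overlaps",
    "assign_sides",
    "side_of_position",
    "build_architecture",
    "tandem_array_stats",
    "clade_summary",
]

NON_DOMAIN_TOKENS = ("TM", "SP")


@dataclasses.dataclass(frozen=True)
class DomainHit:
    protein_id: str
    accession: str
    start: int
    end: int
    score: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.protein_id}: start > end")


@dataclasses.dataclass(frozen=True)
class Token:
    name: str  # domain group name, or "TM" / "SP"
    start: int
    end: int
    side: str  # cytoplasmic | periplasmic | membrane | n/a


@dataclasses.dataclass(frozen=True)
class ProteinArchitecture:
    protein_id: str
    tokens: tuple[Token, ...]
    n_tm: int
    has_signal: bool

    @property
    def token_string(self) -> str:
        return "-".join(t.name for t in self.tokens)

    def domain_tokens(self) -> tuple[Token, ...]:
        return tuple(t for t in self.tokens if t.name not in NON_DOMAIN_TOKENS)


def _overlap(a: DomainHit, b: DomainHit) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def resolve_domain_overlaps(hits: Sequence[DomainHit]) -> list[DomainHit]:
    """Greedy best-score-first overlap resolution.

    A hit is kept when it overlaps every already-kept hit by less than 50% of
    the shorter of the two intervals.  Ties in score break by (accession,
    start), so the kept set does not depend on input order.
    """
    ordered = sorted(hits, key=lambda h: (-h.score, h.accession, h.start, h.end))
    kept: list[DomainHit] = []
    for h in ordered:
        ok = True
        for k in kept:
            shorter = min(h.end - h.start + 1, k.end - k.start + 1)
            if _overlap(h, k) >= 0.5 * shorter:
                ok = False
                break
        if ok:
            kept.append(h)
    kept.sort(key=lambda h: (h.start, h.end, h.accession))
    return kept


_SIDE_OF_KIND = {
    "inside": "cytoplasmic",
    "outside": "periplasmic",
    "TMhelix": "membrane",
    "signal": "n/a",
}


def assign_sides(
    segments: Sequence[Segment], protein_id: str = ""
) -> list[tuple[Segment, str]]:
    """Side label for every topological segment of one protein.

    Explicit inside/outside labels are honoured (and checked: the two sides
    flanking a TM helix must differ).  Topologies carrying only TM helices
    (and optionally a signal) get sides inferred by parity, with synthetic
    inside/outside segments created for the inter-helix stretches.
    """
    segs = sorted(segments, key=lambda s: s.start)
    has_labels = any(s.kind in ("inside", "outside") for s in segs)
    if has_labels:
        labelled = [(s, _SIDE_OF_KIND[s.kind]) for s in segs]
        flanked = [s for s in segs if s.kind in ("inside", "outside")]
        tms = [s for s in segs if s.kind == "TMhelix"]
        for tm in tms:
            before = [s for s in flanked if s.end < tm.start]
            after = [s for s in flanked if s.start > tm.end]
            if before and after and before[-1].kind == after[0].kind:
                raise ValueError(
                    f"{protein_id or 'protein'}: same side "
                    f"({before[-1].kind}) on both flanks of TM helix "
                    f"[{tm.start},{tm.end}]"
                )
        return labelled

    # parity inference from TM helices alone
    out: list[tuple[Segment, str]] = []
    has_signal = any(s.kind == "signal" for s in segs)
    side = "periplasmic" if has_signal else "cytoplasmic"
    length = max((s.end for s in segs), default=0)
    pos = 1
    events = [s for s in segs if s.kind in ("signal", "TMhelix")]
    for seg in events:
        if seg.start > pos:
            out.append((Segment("inside" if side == "cytoplasmic" else "outside",
                                pos, seg.start - 1), side))
        out.append((seg, _SIDE_OF_KIND[seg.kind]))
        if seg.kind == "TMhelix":
            side = "periplasmic" if side == "cytoplasmic" else "cytoplasmic"
        pos = seg.end + 1
    # trailing segment runs to the end of the chain; the chain length is not
    # part of a TM-only topology, so it is left open-ended
    end = max(length, pos)
    out.append((Segment("inside" if side == "cytoplasmic" else "outside",
                        pos, end), side))
    return out


def side_of_position(
    sided_segments: Sequence[tuple[Segment, str]], pos: int
) -> str:
    for seg, side in sided_segments:
        if seg.start <= pos <= seg.end:
            return side
    # past the last annotated segment: use the last side
    return sided_segments[-1][1] if sided_segments else "cytoplasmic"


def build_architecture(
    protein_id: str,
    domains: Sequence[DomainHit],
    topology: Sequence[Segment],
    groups: Mapping[str, str],
    protein_length: int | None = None,
    resolve_overlaps: bool = True,
) -> ProteinArchitecture:
    """Ordered token string with per-token sidedness for one protein.

    Domain accessions are collapsed to group names via ``groups`` (unmapped
    accessions keep their accession as the group).  A domain whose span
    crosses a TM helix is labelled "membrane" with a warning.
    """
    if protein_length is not None:
        for d in domains:
            if d.end > protein_length:
                raise ValueError(
                    f"{protein_id}: domain [{d.start},{d.end}] beyond "
                    f"protein length {protein_length}"
                )
    hits = resolve_domain_overlaps(domains) if resolve_overlaps else sorted(
        domains, key=lambda h: (h.start, h.end, h.accession)
    )
    sided = assign_sides(topology, protein_id)
    tms = [s for s in topology if s.kind == "TMhelix"]
    tokens: list[Token] = []
    for d in hits:
        crossing = any(d.start < tm.start and d.end > tm.end for tm in tms)
        if crossing:
            warnings.warn(
                f"{protein_id}: domain {d.accession} [{d.start},{d.end}] "
                "spans a TM helix; side set to membrane"
            )
            side = "membrane"
        else:
            mid = (d.start + d.end) // 2
            side = side_of_position(sided, mid)
        tokens.append(Token(groups.get(d.accession, d.accession),
                            d.start, d.end, side))
    for s in topology:
        if s.kind == "TMhelix":
            tokens.append(Token("TM", s.start, s.end, "membrane"))
        elif s.kind == "signal":
            tokens.append(Token("SP", s.start, s.end, "n/a"))
    tokens.sort(key=lambda t: (t.start, t.end, t.name))
    return ProteinArchitecture(
        protein_id=protein_id,
        tokens=tuple(tokens),
        n_tm=sum(1 for s in topology if s.kind == "TMhelix"),
        has_signal=any(s.kind == "signal" for s in topology),
    )


@dataclasses.dataclass(frozen=True)
class TandemArrayStats:
    group: str
    per_protein: pd.DataFrame  # protein_id, longest_run, total_copies
    total_domains: int
    n_proteins: int  # proteins containing >= 1 copy
    mean_copies_per_protein: float
    max_run: int


def tandem_array_stats(
    architectures: Iterable[ProteinArchitecture], group: str
) -> TandemArrayStats:
    """Per-protein tandem-run lengths and cohort totals for one domain group.

    A run is a maximal stretch of consecutive *domain* tokens of the group:
    another domain group breaks a run, TM/SP tokens do not.
    """
    rows = []
    for arch in architectures:
        run = longest = total = 0
        for tok in arch.domain_tokens():
            if tok.name == group:
                run += 1
                total += 1
                longest = max(longest, run)
            else:
                run = 0
        if total:
            rows.append({"protein_id": arch.protein_id,
                         "longest_run": longest, "total_copies": total})
    per_protein = pd.DataFrame(
        rows, columns=["protein_id", "longest_run", "total_copies"]
    )
    total_domains = int(per_protein["total_copies"].sum()) if len(per_protein) else 0
    n_proteins = len(per_protein)
    return TandemArrayStats(
        group=group,
        per_protein=per_protein,
        total_domains=total_domains,
        n_proteins=n_proteins,
        mean_copies_per_protein=(total_domains / n_proteins) if n_proteins else 0.0,
        max_run=int(per_protein["longest_run"].max()) if n_proteins else 0,
    )


def clade_summary(
    census: pd.DataFrame, clade_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-clade mean/min/max of total and membrane STK counts.

    ``census`` needs columns taxon, proteome_size, n_putative, n_membrane
    (one row per taxon).  Every taxon must be mapped to a clade.
    """
    unmapped = sorted(set(census["taxon"]) - set(clade_map))
    if unmapped:
        raise ValueError(f"taxa without a clade: {unmapped}")
    df = census.copy()
    df["clade"] = df["taxon"].map(clade_map)
    df["fraction"] = df["n_putative"] / df["proteome_size"]
    agg = df.groupby("clade").agg(
        n_taxa=("taxon", "size"),
        stk_mean=("n_putative", "mean"),
        stk_min=("n_putative", "min"),
        stk_max=("n_putative", "max"),
        tm_stk_mean=("n_membrane", "mean"),
        tm_stk_min=("n_membrane", "min"),
        tm_stk_max=("n_membrane", "max"),
        fraction_mean=("fraction", "mean"),
    )
    return agg.reset_index()
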