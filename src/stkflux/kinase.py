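"""Classification of Ser/Thr protein kinases from Pkinase (PF00069) profile hits.

Bacterial eukaryotic-like Ser/Thr kinases (STKs) carry a ~250-300 residue
catalytic Pkinase domain whose activity requires three residues: a lysine in
subdomain II (the "K") and two aspartates in subdomains VIb and VII ("D1" and
"D2").  A protein is called a *functional* STK when its Pkinase hit(s) jointly
cover (most of) the profile model and align the catalytic K/D/D residues to
the expected model columns; a protein with Pkinase evidence that fails either
test is a *putative nonfunctional* STK; anything else is not a kinase.

Hits arrive as per-domain rows from a profile search (hmmsearch domtblout
dialect) plus the aligned query string in model-column register.  A single
protein may carry several partial hits; fragments are stitched by taking the
union of their model-coordinate spans before the completeness and catalytic
checks, so a kinase split across two hit rows is still recognised.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "DomainInstance",
    "KddSpec",
    "KinaseCall",
    "CensusRow",
    "residue_at_model_column",
    "check_kdd",
    "stitch_and_classify",
    "classify_proteins",
    "proteome_kinase_census",
]

PKINASE_ACC = "PF00069"


@dataclasses.dataclass(frozen=True)
class DomainInstance:
    """One profile-model hit on a protein.

    Coordinates are 1-based inclusive.  ``aligned_query`` holds one character
    per model column in ``[hmm_start, hmm_end]``; deletions relative to the
    model are ``-``.  Insertions relative to the model are not represented
    (they carry no model column and never enter the catalytic-site check).
    """

    protein_id: str
    model_id: str
    env_start: int
    env_end: int
    hmm_start: int
    hmm_end: int
    aligned_query: str = ""
    bitscore: float = 0.0
    evalue: float = 0.0

    def __post_init__(self) -> None:
        if self.hmm_start > self.hmm_end:
            raise ValueError(
                f"{self.protein_id}: hmm_start {self.hmm_start} > hmm_end {self.hmm_end}"
            )
        if self.env_start > self.env_end:
            raise ValueError(
                f"{self.protein_id}: env_start {self.env_start} > env_end {self.env_end}"
            )
        if self.aligned_query:
            span = self.hmm_end - self.hmm_start + 1
            if len(self.aligned_query) != span:
                raise ValueError(
                    f"{self.protein_id}: aligned_query length {len(self.aligned_query)} "
                    f"does not match model span {span}"
                )


@dataclasses.dataclass(frozen=True)
class KddSpec:
    """Model-column coordinates of the catalytic K/D1/D2 residues.

    Column numbers are profile-model specific (they drift between Pfam
    releases), so they are configuration, never hard-coded.  ``allowed_K`` and
    ``allowed_D`` are conservative by default: only the canonical residue
    satisfies a site.
    """

    model_length: int
    pos_K: int
    pos_D1: int
    pos_D2: int
    allowed_K: frozenset[str] = frozenset("K")
    allowed_D: frozenset[str] = frozenset("D")

    def __post_init__(self) -> None:
        if not (1 <= self.pos_K < self.pos_D1 < self.pos_D2 <= self.model_length):
            raise ValueError(
                "require 1 <= pos_K < pos_D1 < pos_D2 <= model_length, got "
                f"K={self.pos_K}, D1={self.pos_D1}, D2={self.pos_D2}, "
                f"L={self.model_length}"
            )

    @classmethod
    def from_yaml(cls, path) -> "KddSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "KddSpec":
        known = {"model_length", "pos_K", "pos_D1", "pos_D2", "allowed_K", "allowed_D"}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown KddSpec keys: {sorted(unknown)}")
        kwargs = dict(raw)
        for key in ("allowed_K", "allowed_D"):
            if key in kwargs:
                kwargs[key] = frozenset(kwargs[key])
        return cls(**kwargs)

    @classmethod
    def default(cls) -> "KddSpec":
        """The packaged spec for the synthetic 264-column Pkinase-like model."""
        with resources.files("stkflux.data").joinpath("kdd_spec_synthetic.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclasses.dataclass(frozen=True)
class KinaseCall:
    protein_id: str
    verdict: str  # functional | putative_nonfunctional | non_kinase
    kdd_found: tuple[bool, bool, bool]
    stitched: bool
    instances_used: tuple[DomainInstance, ...]
    coverage_fraction: float


@dataclasses.dataclass(frozen=True)
class CensusRow:
    taxon: str
    proteome_size: int
    n_putative: int  # functional + putative_nonfunctional
    n_functional: int
    n_membrane: int  # putative STKs with >= 1 TM helix
    functional_fraction: float


def residue_at_model_column(inst: DomainInstance, col: int) -> str | None:
    """Query residue aligned to model column ``col``, or None.

    None is returned when the column lies outside the instance's model span,
    or when the query has a deletion at that column.
    """
    if col < inst.hmm_start or col > inst.hmm_end:
        return None
    if not inst.aligned_query:
        return None
    res = inst.aligned_query[col - inst.hmm_start]
    if res in "-.":
        return None
    return res


def check_kdd(
    instances: Sequence[DomainInstance], spec: KddSpec
) -> tuple[bool, bool, bool]:
    """Catalytic-site check over the stitched union of hits.

    A site is satisfied when ANY instance aligns an allowed residue to its
    model column, so fragments that jointly carry K, D1 and D2 pass.
    """
    found = [False, False, False]
    sites = (
        (spec.pos_K, spec.allowed_K),
        (spec.pos_D1, spec.allowed_D),
        (spec.pos_D2, spec.allowed_D),
    )
    for inst in instances:
        for i, (pos, allowed) in enumerate(sites):
            if found[i]:
                continue
            res = residue_at_model_column(inst, pos)
            if res is not None and res.upper() in allowed:
                found[i] = True
    return tuple(found)  # type: ignore[return-value]


def _model_coverage(instances: Sequence[DomainInstance], model_length: int) -> float:
    spans = sorted((i.hmm_start, i.hmm_end) for i in instances)
    covered = 0
    cur_start = cur_end = None
    for s, e in spans:
        if cur_end is None or s > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = s, e
        else:
            cur_end = max(cur_end, e)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered / model_length


def stitch_and_classify(
    instances: Sequence[DomainInstance],
    spec: KddSpec,
    min_model_coverage: float = 0.8,
) -> KinaseCall:
    """Classify one protein from all its Pkinase hits.

    functional: model coverage >= ``min_model_coverage`` AND all of K, D1, D2
    aligned to allowed residues (over the stitched union of hits).
    putative_nonfunctional: at least one Pkinase hit, functional criteria fail.
    non_kinase: no Pkinase hit.
    """
    insts = tuple(
        sorted(
            (i for i in instances if i.model_id == PKINASE_ACC),
            key=lambda i: (i.hmm_start, i.hmm_end, i.env_start),
        )
    )
    if not insts:
        pid = instances[0].protein_id if instances else ""
        return KinaseCall(pid, "non_kinase", (False, False, False), False, (), 0.0)
    pid = insts[0].protein_id
    # De-duplicate identical rows so verdicts are invariant to row duplication.
    insts = tuple(dict.fromkeys(insts))
    coverage = _model_coverage(insts, spec.model_length)
    kdd = check_kdd(insts, spec)
    verdict = (
        "functional"
        if coverage >= min_model_coverage and all(kdd)
        else "putative_nonfunctional"
    )
    return KinaseCall(pid, verdict, kdd, len(insts) > 1, insts, coverage)


def classify_proteins(
    instances: Iterable[DomainInstance],
    spec: KddSpec,
    min_model_coverage: float = 0.8,
) -> dict[str, KinaseCall]:
    """Group hit rows by protein and classify each protein."""
    by_protein: dict[str, list[DomainInstance]] = {}
    for inst in instances:
        by_protein.setdefault(inst.protein_id, []).append(inst)
    return {
        pid: stitch_and_classify(rows, spec, min_model_coverage)
        for pid, rows in sorted(by_protein.items())
    }


def proteome_kinase_census(
    calls: Sequence[KinaseCall],
    proteome_size: int,
    tm_table: Mapping[str, Sequence] | None = None,
    taxon: str = "",
) -> CensusRow:
    """Per-proteome STK tallies (putative, functional, membrane-associated).

    ``tm_table`` maps protein_id to topology segments; a putative STK counts
    as membrane-associated when it has at least one TM helix segment.
    """
    if proteome_size <= 0:
        raise ValueError("proteome_size must be positive")
    putative = [c for c in calls if c.verdict in ("functional", "putative_nonfunctional")]
    functional = [c for c in calls if c.verdict == "functional"]
    n_membrane = 0
    if tm_table is not None:
        for call in putative:
            segments = tm_table.get(call.protein_id, ())
            if any(getattr(seg, "kind", None) == "TMhelix" for seg in segments):
                n_membrane += 1
    return CensusRow(
        taxon=taxon,
        proteome_size=proteome_size,
        n_putative=len(putative),
        n_functional=len(functional),
        n_membrane=n_membrane,
        functional_fraction=len(functional) / proteome_size,
    )
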