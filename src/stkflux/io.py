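"""Readers and writers for every format the pipeline consumes or emits.

Dialects handled here: newick species trees (via dendropy), FASTA alignments
(via Biopython), family-by-taxon profile TSVs, hmmsearch ``--domtblout``
per-domain tables plus a companion alignment TSV, InterProScan-style domain
TSVs, DeepTMHMM-style GFF3 topology files, tabular homology hits with COG
annotations, and the dN/dS digest table.

All coordinates, in files and in memory, are 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .cog import CogHit
from .composition import CodonAlignment, ProteinAlignment
from .kinase import DomainInstance

__all__ = [
    "SpeciesTree",
    "Segment",
    "TopologyTable",
    "read_newick",
    "read_fasta_alignment",
    "read_codon_alignment",
    "write_fasta",
    "read_profile_tsv",
    "write_profile_tsv",
    "read_domtbl",
    "write_domtbl",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "attach_alignments",
    "read_topology_gff3",
    "write_topology_gff3",
    "read_interproscan_tsv",
    "write_interproscan_tsv",
    "read_group_map",
    "read_clade_map",
    "read_cog_hits",
    "read_dnds_table",
]


# ---------------------------------------------------------------------------
# species tree


class SpeciesTree:
    """A rooted species tree with stable node identifiers.

    Leaves are identified by their taxon labels; unlabeled internal nodes get
    ``N0`` (root), ``N1``, ... in preorder.  Multifurcations are preserved.
    """

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        self._index()

    def _index(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        dupes = {x for x in labels if labels.count(x) > 1}
        if dupes:
            raise ValueError(f"duplicate leaf names: {sorted(dupes)}")
        counter = 0
        self.node_ids: dict[int, str] = {}
        for node in self.tree.preorder_node_iter():
            if node.is_leaf():
                nid = node.taxon.label
            elif node.label:
                nid = node.label
            else:
                nid = f"N{counter}"
                counter += 1
            self.node_ids[id(node)] = nid
        self.leaves = labels
        root = self.tree.seed_node
        self.root_id = self.node_ids[id(root)]
        if len(root.child_nodes()) > 2:
            warnings.warn("root is a polytomy; treating it as given (rooted)")
        self.children: dict[str, list[str]] = {}
        self.parent: dict[str, str] = {}
        for node in self.tree.preorder_node_iter():
            nid = self.node_ids[id(node)]
            kids = [self.node_ids[id(c)] for c in node.child_nodes()]
            self.children[nid] = kids
            for k in kids:
                self.parent[k] = nid
        self.postorder = [
            self.node_ids[id(n)] for n in self.tree.postorder_node_iter()
        ]
        self.preorder = [
            self.node_ids[id(n)] for n in self.tree.preorder_node_iter()
        ]
        self.branches: list[tuple[str, str]] = [
            (self.parent[n], n) for n in self.preorder if n != self.root_id
        ]

    @classmethod
    def from_string(cls, newick: str) -> "SpeciesTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", rooting="force-rooted"
            )
        except dendropy.utility.error.DataParseError as exc:
            if "Duplicate taxon" in str(exc):
                raise ValueError(f"duplicate leaf names in newick: {exc}") from exc
            raise
        return cls(tree)

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()


def read_newick(path) -> SpeciesTree:
    with open(path) as fh:
        return SpeciesTree.from_string(fh.read())


# ---------------------------------------------------------------------------
# FASTA


def read_fasta_alignment(path) -> ProteinAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return ProteinAlignment(
        taxa=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
    )


def read_codon_alignment(path, gene_id: str | None = None) -> CodonAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    return CodonAlignment(
        gene_id=gene_id or Path(path).stem,
        taxa=tuple(r.id for r in records),
        sequences=tuple(str(r.seq) for r in records),
    )


def write_fasta(path, names: Sequence[str], sequences: Sequence[str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in zip(names, sequences)
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# phyletic profile


def read_profile_tsv(path) -> pd.DataFrame:
    """Family-by-taxon count matrix; first column ``family_id``."""
    df = pd.read_csv(path, sep="\t", index_col="family_id")
    if (df.values < 0).any():
        raise ValueError("negative counts in profile")
    return df.astype(int)


def write_profile_tsv(path, profile: pd.DataFrame) -> None:
    profile.to_csv(path, sep="\t", index_label="family_id")


# ---------------------------------------------------------------------------
# domtblout dialect

_DOMTBL_HEADER = (
    "#                                                               "
    "--- full sequence --- -------------- this domain -------------   "
    "hmm coord   ali coord   env coord\n"
    "# target name        accession   tlen query name           "
    "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
    "i-Evalue  score  bias  from    to  from    to  from    to  acc "
    "description of target\n"
)


def write_domtbl(path, instances: Sequence[DomainInstance], *,
                 target_lengths: Mapping[str, int] | None = None,
                 model_name: str = "Pkinase",
                 model_length: int = 264) -> None:
    """Write per-domain rows in the hmmsearch ``--domtblout`` column layout."""
    by_protein: dict[str, list[DomainInstance]] = {}
    for inst in instances:
        by_protein.setdefault(inst.protein_id, []).append(inst)
    with open(path, "w") as fh:
        fh.write(_DOMTBL_HEADER)
        for pid in by_protein:
            rows = by_protein[pid]
            tlen = (target_lengths or {}).get(pid, max(r.env_end for r in rows))
            for i, inst in enumerate(rows, start=1):
                fh.write(
                    f"{pid:<20s} -          {tlen:5d} {model_name:<20s} "
                    f"{inst.model_id:<10s} {model_length:5d} "
                    f"{inst.evalue:9.2g} {inst.bitscore:6.1f}   0.0 "
                    f"{i:3d} {len(rows):3d} {inst.evalue:9.2g} {inst.evalue:9.2g} "
                    f"{inst.bitscore:6.1f}   0.0 "
                    f"{inst.hmm_start:5d} {inst.hmm_end:5d} "
                    f"{inst.env_start:5d} {inst.env_end:5d} "
                    f"{inst.env_start:5d} {inst.env_end:5d} 0.99 -\n"
                )


def read_domtbl(path) -> list[DomainInstance]:
    """Parse a domtblout-dialect file into DomainInstances (no alignments)."""
    instances = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 22:
                raise ValueError(f"{path}:{lineno}: malformed domtblout row")
            try:
                inst = DomainInstance(
                    protein_id=fields[0],
                    model_id=fields[4],
                    evalue=float(fields[12]),
                    bitscore=float(fields[13]),
                    hmm_start=int(fields[15]),
                    hmm_end=int(fields[16]),
                    env_start=int(fields[19]),
                    env_end=int(fields[20]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            instances.append(inst)
    return instances


def write_alignment_tsv(path, instances: Sequence[DomainInstance]) -> None:
    """Companion table carrying the model-register alignment strings."""
    with open(path, "w") as fh:
        fh.write("protein_id\thmm_start\thmm_end\taligned_query\n")
        for inst in instances:
            fh.write(
                f"{inst.protein_id}\t{inst.hmm_start}\t{inst.hmm_end}\t"
                f"{inst.aligned_query}\n"
            )


def read_alignment_tsv(path) -> dict[tuple[str, int, int], str]:
    df = pd.read_csv(path, sep="\t")
    return {
        (r.protein_id, int(r.hmm_start), int(r.hmm_end)): str(r.aligned_query)
        for r in df.itertuples()
    }


def attach_alignments(
    instances: Sequence[DomainInstance],
    alignments: Mapping[tuple[str, int, int], str],
) -> list[DomainInstance]:
    out = []
    for inst in instances:
        key = (inst.protein_id, inst.hmm_start, inst.hmm_end)
        aq = alignments.get(key, "")
        out.append(dataclasses.replace(inst, aligned_query=aq))
    return out


# ---------------------------------------------------------------------------
# topology GFF3

TOPOLOGY_KINDS = ("signal", "TMhelix", "inside", "outside")


@dataclasses.dataclass(frozen=True)
class Segment:
    kind: str  # signal | TMhelix | inside | outside
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGY_KINDS:
            raise ValueError(f"unknown topology kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")


TopologyTable = dict[str, list[Segment]]


def write_topology_gff3(path, table: TopologyTable) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for pid in table:
            for seg in table[pid]:
                fh.write(
                    f"{pid}\tstkflux\t{seg.kind}\t{seg.start}\t{seg.end}\t.\t.\t.\t.\n"
                )


def read_topology_gff3(path) -> TopologyTable:
    """Parse signal/TMhelix/inside/outside features; validate per protein.

    Segments must be non-overlapping; they are returned sorted by start.
    """
    table: TopologyTable = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ValueError(f"{path}:{lineno}: malformed GFF3 row")
            pid, _, kind, start, end = fields[:5]
            if kind not in TOPOLOGY_KINDS:
                continue
            table.setdefault(pid, []).append(Segment(kind, int(start), int(end)))
    for pid, segs in table.items():
        segs.sort(key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{pid}: overlapping topology segments "
                    f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                )
    return table


# ---------------------------------------------------------------------------
# InterProScan-style domain TSV


def write_interproscan_tsv(path, rows: Iterable[tuple]) -> None:
    """Rows: (protein_id, accession, description, start, end, score)."""
    with open(path, "w") as fh:
        fh.write("protein_id\taccession\tdescription\tstart\tend\tscore\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_interproscan_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "accession", "start", "end", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_group_map(path) -> dict[str, str]:
    """Accession -> domain group name TSV (columns accession, group)."""
    df = pd.read_csv(path, sep="\t")
    if df["accession"].duplicated().any():
        dupes = df.loc[df["accession"].duplicated(), "accession"].tolist()
        raise ValueError(f"accessions mapped to more than one group: {dupes}")
    return dict(zip(df["accession"], df["group"]))


def read_clade_map(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["taxon"], df["clade"]))


# ---------------------------------------------------------------------------
# COG hits and dN/dS digest


def read_cog_hits(path, evalue_cutoff: float = 1e-5) -> list[CogHit]:
    """Outfmt-6-style TSV with added cog_id and category columns.

    Columns: query_id, q_start, q_end, cog_id, category, evalue.  Hits above
    the e-value cutoff are dropped.
    """
    df = pd.read_csv(path, sep="\t")
    hits = []
    for r in df.itertuples():
        if float(r.evalue) > evalue_cutoff:
            continue
        hits.append(
            CogHit(
                query_id=str(r.query_id),
                q_start=int(r.q_start),
                q_end=int(r.q_end),
                cog_id=str(r.cog_id),
                category=str(r.category),
                evalue=float(r.evalue),
            )
        )
    return hits


def read_dnds_table(path) -> pd.DataFrame:
    """codeml-digest table with columns gene_id, dN, dS (per-gene means)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "dN", "dS"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df
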