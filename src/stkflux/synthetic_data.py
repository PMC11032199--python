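"""Synthetic inputs with known ground truth for every pipeline stage.

Real inputs to this pipeline are genome-scale third-party artifacts (codon
alignments, orthology matrices, profile-search hit tables, domain and
topology predictions).  This module generates small, fully controlled
stand-ins for each of them, together with the ground truth needed to score
the corresponding stage exactly:

* codon alignments with per-taxon GC targets at codon positions 1-2
  (realized fractions are returned alongside);
* presence/absence profiles evolved root-to-leaves on a species tree with
  per-branch gain/loss probabilities and a complete event log;
* Pkinase-like domain-hit tables covering every decision branch of the
  kinase classifier (catalytic residues present/substituted, whole/split/
  incomplete domains), with intended labels;
* domain-annotation and membrane-topology fixtures with tandem TPR/WD40
  arrays of known lengths and known per-domain sidedness.

Everything is driven by one ``SimConfig``; identical configs (including the
seed) give byte-identical outputs.  Sequence content is compositionally
controlled but otherwise i.i.d. — no substitution-model realism is attempted.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .architecture import DomainHit
from .composition import AMINO_ACIDS, CodonAlignment
from .flux import PhyleticProfile
from .io import (
    Segment,
    SpeciesTree,
    TopologyTable,
    write_alignment_tsv,
    write_domtbl,
    write_fasta,
    write_interproscan_tsv,
    write_profile_tsv,
    write_topology_gff3,
)
from .kinase import PKINASE_ACC, DomainInstance, KddSpec

__all__ = [
    "SimConfig",
    "GainLossEvent",
    "KinaseFixture",
    "ArchitectureFixture",
    "TruthArchitecture",
    "gen_species_tree",
    "gen_codon_alignment",
    "gen_bias_gene_set",
    "gen_phyletic_profiles",
    "gen_kinase_hit_table",
    "gen_architecture_fixtures",
    "write_all",
]

KINASE_CLASSES = (
    "functional",
    "missing_K",
    "missing_D1",
    "missing_D2",
    "fragmented_functional",
    "fragmented_incomplete",
)

# intended classifier verdict per fixture class
TRUTH_VERDICT = {
    "functional": "functional",
    "fragmented_functional": "functional",
    "missing_K": "putative_nonfunctional",
    "missing_D1": "putative_nonfunctional",
    "missing_D2": "putative_nonfunctional",
    "fragmented_incomplete": "putative_nonfunctional",
}

GROUP_ACCESSIONS = {
    "Pkinase": ("PF00069",),
    "TPR": ("PF00515", "PF07719", "PF13176"),
    "WD40": ("PF00400",),
}
DOMAIN_LENGTHS = {"Pkinase": 264, "TPR": 34, "WD40": 40}
TM_LENGTH = 21
SIGNAL_LENGTH = 22


@dataclasses.dataclass
class SimConfig:
    """Study conditions for every generator; one seed drives everything."""

    seed: int = 1
    n_taxa: int = 12
    tree_shape: str = "random-yule"  # balanced | caterpillar | random-yule
    gc_targets: Mapping[str, float] | None = None  # default: spread 0.35..0.65
    n_genes: int = 114
    gene_length_codons: int = 300
    family_gain_rate: float = 0.05
    family_loss_rate: float = 0.05
    root_presence_prob: float = 0.5
    n_families: int = 500
    kinase_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {c: 200 for c in KINASE_CLASSES}
    )
    kdd_spec: KddSpec = dataclasses.field(default_factory=KddSpec.default)
    architecture_palette: Sequence[tuple[str, tuple[int, int]]] = (
        ("Pkinase", (1, 1)),
        ("TPR", (1, 15)),
        ("WD40", (1, 19)),
    )
    n_arch_proteins: int = 200
    tm_span_range: tuple[int, int] = (0, 3)
    signal_prob: float = 0.3

    def __post_init__(self) -> None:
        for name in ("family_gain_rate", "family_loss_rate",
                     "root_presence_prob", "signal_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.gc_targets is not None:
            bad = {t: f for t, f in self.gc_targets.items() if not 0 <= f <= 1}
            if bad:
                raise ValueError(f"gc_targets outside [0,1]: {bad}")
        for name in ("n_taxa", "n_genes", "gene_length_codons", "n_families",
                     "n_arch_proteins"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_taxa < 2:
            raise ValueError("need at least 2 taxa")
        unknown = set(self.kinase_counts) - set(KINASE_CLASSES)
        if unknown:
            raise ValueError(f"unknown kinase classes: {sorted(unknown)}")
        if any(v < 0 for v in self.kinase_counts.values()):
            raise ValueError("kinase counts must be >= 0")
        if not self.architecture_palette:
            raise ValueError("architecture_palette must be non-empty")
        lo, hi = self.tm_span_range
        if lo < 0 or hi < lo:
            raise ValueError(f"bad tm_span_range {self.tm_span_range}")

    def taxa(self) -> list[str]:
        return [f"T{i:02d}" for i in range(1, self.n_taxa + 1)]

    def resolved_gc_targets(self) -> dict[str, float]:
        if self.gc_targets is not None:
            return dict(self.gc_targets)
        taxa = self.taxa()
        vals = np.linspace(0.35, 0.65, len(taxa))
        return dict(zip(taxa, vals))

    def _rng(self, stream: int) -> np.random.Generator:
        # one independent stream per generator, all derived from the one seed
        return np.random.default_rng([self.seed, stream])


# ---------------------------------------------------------------------------
# species tree


def gen_species_tree(config: SimConfig) -> SpeciesTree:
    taxa = config.taxa()
    if config.tree_shape == "caterpillar":
        nwk = taxa[-1]
        for t in reversed(taxa[:-1]):
            nwk = f"({t},{nwk})"
    elif config.tree_shape == "balanced":
        def build(names: list[str]) -> str:
            if len(names) == 1:
                return names[0]
            mid = len(names) // 2
            return f"({build(names[:mid])},{build(names[mid:])})"
        nwk = build(taxa)
    elif config.tree_shape == "random-yule":
        # Yule growth: split a uniformly chosen extant tip at each step
        rng = config._rng(0)
        root: list = [taxa[0], taxa[1]]
        tips: list[tuple[list, int]] = [(root, 0), (root, 1)]
        for t in taxa[2:]:
            holder, idx = tips.pop(int(rng.integers(len(tips))))
            node = [holder[idx], t]
            holder[idx] = node
            tips.extend([(node, 0), (node, 1)])

        def serialize(node) -> str:
            if isinstance(node, str):
                return node
            return "(" + ",".join(serialize(c) for c in node) + ")"

        nwk = serialize(root)
    else:
        raise ValueError(f"unknown tree_shape {config.tree_shape!r}")
    return SpeciesTree.from_string(nwk + ";")


# ---------------------------------------------------------------------------
# codon alignments


def gen_codon_alignment(
    config: SimConfig,
    gene_id: str = "g0001",
    gc_targets: Mapping[str, float] | None = None,
    stream: int = 1,
) -> tuple[CodonAlignment, dict[str, float]]:
    """One gap-free in-frame alignment with controlled position-1/2 GC.

    For every codon, positions 1 and 2 are drawn G/C with the taxon's target
    probability (G vs C equiprobable) and A/T otherwise; position 3 is
    uniform over ACGT.  Returns the alignment and the realized per-taxon
    G/C fractions at positions 1-2.
    """
    targets = dict(gc_targets) if gc_targets is not None else config.resolved_gc_targets()
    if not targets:
        raise ValueError("empty taxon set")
    bad = {t: f for t, f in targets.items() if not 0 <= f <= 1}
    if bad:
        raise ValueError(f"gc_targets outside [0,1]: {bad}")
    if config.gene_length_codons < 1:
        raise ValueError("gene_length_codons must be >= 1")
    rng = config._rng(stream)
    n = config.gene_length_codons
    taxa, seqs, realized = [], [], {}
    gc_chars = np.array(list("GC"))
    at_chars = np.array(list("AT"))
    all_chars = np.array(list("ACGT"))
    for taxon in sorted(targets):
        p = targets[taxon]
        is_gc = rng.random((n, 2)) < p
        strong = gc_chars[rng.integers(0, 2, size=(n, 2))]
        weak = at_chars[rng.integers(0, 2, size=(n, 2))]
        pos12 = np.where(is_gc, strong, weak)
        pos3 = all_chars[rng.integers(0, 4, size=(n, 1))]
        codons = np.concatenate([pos12, pos3], axis=1)
        seq = "".join(codons.ravel())
        taxa.append(taxon)
        seqs.append(seq)
        realized[taxon] = float(is_gc.mean())
    aln = CodonAlignment(gene_id=gene_id, taxa=tuple(taxa), sequences=tuple(seqs))
    return aln, realized


def gen_bias_gene_set(
    config: SimConfig,
) -> tuple[list[CodonAlignment], pd.DataFrame]:
    """A gene set with graded compositional bias and a correlated dN table.

    Gene i gets per-taxon GC targets 0.5 + d_i * z_t, where z_t is a fixed
    centred spread across taxa and the per-gene dispersion d_i is uniform on
    [0, 0.3].  The dN digest is d_i plus noise, giving the positive
    aminoGC-sd/dN correlation seen for fast-evolving genes.
    """
    rng = config._rng(2)
    taxa = config.taxa()
    z = np.linspace(-1.0, 1.0, len(taxa))
    alignments = []
    rows = []
    for i in range(config.n_genes):
        gid = f"g{i + 1:04d}"
        d = float(rng.uniform(0.0, 0.3))
        targets = {t: float(np.clip(0.5 + d * zt, 0.0, 1.0))
                   for t, zt in zip(taxa, z)}
        aln, _ = gen_codon_alignment(config, gene_id=gid, gc_targets=targets,
                                     stream=1000 + i)
        alignments.append(aln)
        dn = max(0.0, 0.8 * d + float(rng.normal(0.0, 0.045)))
        ds = float(rng.uniform(0.5, 2.0))
        rows.append({"gene_id": gid, "dN": round(dn, 6), "dS": round(ds, 6)})
    return alignments, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# phyletic profiles


@dataclasses.dataclass(frozen=True)
class GainLossEvent:
    family: str
    parent: str
    child: str
    kind: str  # gain | loss


def gen_phyletic_profiles(
    config: SimConfig, tree: SpeciesTree
) -> tuple[PhyleticProfile, list[GainLossEvent]]:
    """Evolve 0/1 family states root-to-leaves; log every gain and loss.

    At most one event happens per branch per family: a present family is
    lost with ``family_loss_rate``, an absent one gained with
    ``family_gain_rate``.
    """
    if len(tree.leaves) < 2:
        raise ValueError("tree must have at least 2 leaves")
    rng = config._rng(3)
    families = [f"fam{i + 1:05d}" for i in range(config.n_families)]
    events: list[GainLossEvent] = []
    leaf_states = np.zeros((config.n_families, len(tree.leaves)), dtype=np.int64)
    leaf_col = {t: j for j, t in enumerate(tree.leaves)}
    for fi, fam in enumerate(families):
        state = {tree.root_id: int(rng.random() < config.root_presence_prob)}
        for parent, child in tree.branches:
            s = state[parent]
            u = rng.random()
            if s == 1 and u < config.family_loss_rate:
                s = 0
                events.append(GainLossEvent(fam, parent, child, "loss"))
            elif s == 0 and u < config.family_gain_rate:
                s = 1
                events.append(GainLossEvent(fam, parent, child, "gain"))
            state[child] = s
        for leaf in tree.leaves:
            leaf_states[fi, leaf_col[leaf]] = state[leaf]
    profile = PhyleticProfile(
        families=tuple(families), taxa=tuple(tree.leaves), counts=leaf_states
    )
    return profile, events


# ---------------------------------------------------------------------------
# kinase hit tables


@dataclasses.dataclass
class KinaseFixture:
    proteins: dict[str, str]  # protein_id -> sequence
    instances: list[DomainInstance]
    truth: dict[str, str]  # protein_id -> fixture class label


def _random_protein(rng: np.random.Generator, length: int) -> np.ndarray:
    aa = np.array(list(AMINO_ACIDS))
    return aa[rng.integers(0, len(aa), size=length)]


def gen_kinase_hit_table(config: SimConfig) -> KinaseFixture:
    """Proteins plus Pkinase-like hits covering every classifier branch.

    Classes: ``functional`` (whole domain, K/D1/D2 at the spec columns);
    ``missing_K``/``missing_D1``/``missing_D2`` (alanine substituted at
    exactly that column); ``fragmented_functional`` (two overlapping hits
    jointly covering the model and jointly carrying KDD);
    ``fragmented_incomplete`` (two hits leaving a model gap over at least one
    catalytic column).
    """
    spec = config.kdd_spec
    rng = config._rng(4)
    proteins: dict[str, str] = {}
    instances: list[DomainInstance] = []
    truth: dict[str, str] = {}
    L = spec.model_length

    for cls in KINASE_CLASSES:
        for i in range(config.kinase_counts.get(cls, 0)):
            pid = f"P_{cls}_{i + 1:04d}"
            domain = _random_protein(rng, L)
            domain[spec.pos_K - 1] = "K"
            domain[spec.pos_D1 - 1] = "D"
            domain[spec.pos_D2 - 1] = "D"
            if cls == "missing_K":
                domain[spec.pos_K - 1] = "A"
            elif cls == "missing_D1":
                domain[spec.pos_D1 - 1] = "A"
            elif cls == "missing_D2":
                domain[spec.pos_D2 - 1] = "A"
            nflank = int(rng.integers(0, 51))
            cflank = int(rng.integers(0, 51))
            seq = (
                "".join(_random_protein(rng, nflank))
                + "".join(domain)
                + "".join(_random_protein(rng, cflank))
            )
            proteins[pid] = seq
            dom_str = "".join(domain)

            def make(hs: int, he: int) -> DomainInstance:
                return DomainInstance(
                    protein_id=pid,
                    model_id=PKINASE_ACC,
                    env_start=nflank + hs,
                    env_end=nflank + he,
                    hmm_start=hs,
                    hmm_end=he,
                    aligned_query=dom_str[hs - 1 : he],
                    bitscore=float(np.round(rng.normal(250.0, 30.0), 1)),
                    evalue=1e-80,
                )

            if cls in ("functional", "missing_K", "missing_D1", "missing_D2"):
                instances.append(make(1, L))
            elif cls == "fragmented_functional":
                # split inside the K..D2 span so neither fragment alone
                # carries all of KDD; overlap keeps the union gap-free
                split = int(rng.integers(spec.pos_K + 5, spec.pos_D1 - 5))
                over = int(rng.integers(5, 21))
                instances.append(make(1, min(split + over, L)))
                instances.append(make(max(1, split - over), L))
            else:  # fragmented_incomplete: model gap covers D1 and D2
                instances.append(make(1, spec.pos_D1 - 5))
                instances.append(make(min(L, spec.pos_D2 + 17), L))
            truth[pid] = TRUTH_VERDICT[cls]
    return KinaseFixture(proteins=proteins, instances=instances, truth=truth)


# ---------------------------------------------------------------------------
# architecture / topology fixtures


@dataclasses.dataclass(frozen=True)
class TruthArchitecture:
    protein_id: str
    length: int
    tokens: tuple[tuple[str, str], ...]  # (token name, intended side)
    array_lengths: Mapping[str, tuple[int, ...]]  # group -> lengths of runs


@dataclasses.dataclass
class ArchitectureFixture:
    domain_hits: list[DomainHit]
    topology: TopologyTable
    truth: list[TruthArchitecture]
    group_map: dict[str, str]


def gen_architecture_fixtures(config: SimConfig) -> ArchitectureFixture:
    """Proteins with known domain arrays, TM topologies and sidedness.

    Each protein gets an optional signal peptide, 0..n TM helices, and one or
    more tandem arrays of palette domains placed in randomly chosen
    topological segments.  The emitted topology carries explicit
    inside/outside labels consistent with the parity rule (N-terminus
    cytoplasmic unless a signal peptide makes the mature chain start
    periplasmic), so label-based and parity-based sidedness always agree on
    these fixtures.
    """
    rng = config._rng(5)
    palette = list(config.architecture_palette)
    group_map = {
        acc: group
        for group, accs in GROUP_ACCESSIONS.items()
        for acc in accs
    }
    hits: list[DomainHit] = []
    topology: TopologyTable = {}
    truths: list[TruthArchitecture] = []

    for i in range(config.n_arch_proteins):
        pid = f"A_{i + 1:05d}"
        has_signal = rng.random() < config.signal_prob
        lo, hi = config.tm_span_range
        n_tm = int(rng.integers(lo, hi + 1))
        n_groups = int(rng.integers(1, min(3, len(palette)) + 1))
        chosen = rng.choice(len(palette), size=n_groups, replace=False)
        arrays = []
        for gi in sorted(chosen):
            group, (amin, amax) = palette[gi]
            arrays.append((group, int(rng.integers(amin, amax + 1)),
                           int(rng.integers(0, n_tm + 1))))

        # lay the protein out left to right, segment by segment
        segments: list[Segment] = []
        token_hits: list[DomainHit] = []
        array_runs: dict[str, list[int]] = {}
        pos = 1
        side = "cytoplasmic"
        if has_signal:
            segments.append(Segment("signal", 1, SIGNAL_LENGTH))
            pos = SIGNAL_LENGTH + 1
            side = "periplasmic"
        for seg_idx in range(n_tm + 1):
            seg_start = pos
            pos += int(rng.integers(5, 26))  # leading linker
            for group, arr_len, target_seg in arrays:
                if target_seg != seg_idx:
                    continue
                dlen = DOMAIN_LENGTHS.get(group, 50)
                accs = GROUP_ACCESSIONS.get(group, (group,))
                for _ in range(arr_len):
                    start, end = pos, pos + dlen - 1
                    acc = str(accs[int(rng.integers(0, len(accs)))])
                    token_hits.append(
                        DomainHit(pid, acc, start, end,
                                  float(np.round(rng.uniform(25.0, 120.0), 1)))
                    )
                    pos = end + 1 + int(rng.integers(1, 6))
                array_runs.setdefault(group, []).append(arr_len)
            pos += int(rng.integers(5, 26))  # trailing linker
            kind = "inside" if side == "cytoplasmic" else "outside"
            segments.append(Segment(kind, seg_start, pos - 1))
            if seg_idx < n_tm:
                segments.append(Segment("TMhelix", pos, pos + TM_LENGTH - 1))
                pos += TM_LENGTH
                side = "periplasmic" if side == "cytoplasmic" else "cytoplasmic"
        length = pos - 1
        hits.extend(token_hits)
        topology[pid] = sorted(segments, key=lambda s: s.start)
        truths.append(
            TruthArchitecture(
                protein_id=pid,
                length=length,
                tokens=tuple(_ordered_tokens(token_hits, segments, group_map)),
                array_lengths={g: tuple(v) for g, v in array_runs.items()},
            )
        )
    return ArchitectureFixture(
        domain_hits=hits, topology=topology, truth=truths, group_map=group_map
    )


def _ordered_tokens(
    token_hits: list[DomainHit],
    segments: list[Segment],
    group_map: Mapping[str, str],
) -> list[tuple[str, str]]:
    side_of = {}
    for seg in segments:
        side_of[(seg.start, seg.end)] = {
            "inside": "cytoplasmic",
            "outside": "periplasmic",
            "TMhelix": "membrane",
            "signal": "n/a",
        }[seg.kind]
    items: list[tuple[int, str, str]] = []
    for h in token_hits:
        mid = (h.start + h.end) // 2
        side = next(
            s for (a, b), s in side_of.items() if a <= mid <= b
        )
        items.append((h.start, group_map.get(h.accession, h.accession), side))
    for seg in segments:
        if seg.kind == "TMhelix":
            items.append((seg.start, "TM", "membrane"))
        elif seg.kind == "signal":
            items.append((seg.start, "SP", "n/a"))
    return [(name, side) for _, name, side in sorted(items)]


# ---------------------------------------------------------------------------
# bundle writer (used by `stkflux simulate`)


def write_all(config: SimConfig, outdir) -> dict[str, Path]:
    """Generate every fixture family and write it under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    tree = gen_species_tree(config)
    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(tree.newick() + "\n")

    profile, events = gen_phyletic_profiles(config, tree)
    paths["profile"] = outdir / "profile.tsv"
    write_profile_tsv(paths["profile"], profile.to_dataframe())
    paths["events"] = outdir / "events.tsv"
    pd.DataFrame([dataclasses.asdict(e) for e in events]).to_csv(
        paths["events"], sep="\t", index=False
    )

    genes_dir = outdir / "genes"
    genes_dir.mkdir(exist_ok=True)
    alignments, dnds = gen_bias_gene_set(config)
    for aln in alignments:
        write_fasta(genes_dir / f"{aln.gene_id}.fasta", aln.taxa, aln.sequences)
    paths["genes"] = genes_dir
    paths["dnds"] = outdir / "dnds.tsv"
    dnds.to_csv(paths["dnds"], sep="\t", index=False)

    kin = gen_kinase_hit_table(config)
    paths["proteins"] = outdir / "proteins.faa"
    write_fasta(paths["proteins"], list(kin.proteins), list(kin.proteins.values()))
    paths["domtbl"] = outdir / "hits.domtbl"
    write_domtbl(
        paths["domtbl"], kin.instances,
        target_lengths={p: len(s) for p, s in kin.proteins.items()},
        model_length=config.kdd_spec.model_length,
    )
    paths["hit_alignments"] = outdir / "hit_alignments.tsv"
    write_alignment_tsv(paths["hit_alignments"], kin.instances)
    paths["kinase_truth"] = outdir / "kinase_truth.tsv"
    pd.DataFrame(
        [{"protein_id": p, "verdict": v} for p, v in kin.truth.items()]
    ).to_csv(paths["kinase_truth"], sep="\t", index=False)

    arch = gen_architecture_fixtures(config)
    paths["domains"] = outdir / "domains.tsv"
    write_interproscan_tsv(
        paths["domains"],
        [
            (h.protein_id, h.accession, arch.group_map.get(h.accession, ""),
             h.start, h.end, h.score)
            for h in arch.domain_hits
        ],
    )
    paths["topology"] = outdir / "topology.gff3"
    write_topology_gff3(paths["topology"], arch.topology)
    paths["groups"] = outdir / "groups.tsv"
    pd.DataFrame(
        [{"accession": a, "group": g} for a, g in sorted(arch.group_map.items())]
    ).to_csv(paths["groups"], sep="\t", index=False)
    paths["arch_truth"] = outdir / "arch_truth.tsv"
    pd.DataFrame(
        [
            {
                "protein_id": t.protein_id,
                "tokens": ";".join(f"{n}:{s}" for n, s in t.tokens),
            }
            for t in arch.truth
        ]
    ).to_csv(paths["arch_truth"], sep="\t", index=False)
    return paths
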