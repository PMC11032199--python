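"""Compositional-bias gene ranking (aminoGC) and stationary alignment trimming.

Phylogenies inferred from taxa with very different genomic GC content tend to
cluster taxa by composition rather than ancestry.  Because most third-codon
changes are synonymous, GC at codon positions 1-2 tracks composition that is
visible at the protein level: the *aminoGC* of a gene in a taxon is the
fraction of G/C among its first and second codon positions, and the standard
deviation of that fraction across taxa measures how compositionally biased
the gene is.  Ranking single-copy genes by this statistic (or by externally
estimated dN) and keeping the least-biased k genes yields concatenates that
are robust to GC attraction.

``stationary_trim`` removes individual alignment sites from a concatenated
protein alignment until the retained sites are compositionally homogeneous
across taxa under a chi-square contingency test (taxa x amino acids).  This is
a contract-level reimplementation of stationary trimming, not a clone of any
particular trimmer: sites are removed greedily, each step dropping the site
whose removal most reduces the chi-square statistic.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CodonAlignment",
    "ProteinAlignment",
    "GeneBiasRecord",
    "GeneDataset",
    "amino_gc",
    "rank_and_select",
    "dataset_overlap",
    "stationary_trim",
    "concatenate_alignments",
]

_NUCS = set("ACGTN-")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass(frozen=True)
class CodonAlignment:
    """In-frame aligned coding sequences; the frame starts at column 1."""

    gene_id: str
    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError(f"{self.gene_id}: taxa/sequence count mismatch")
        if not self.taxa:
            raise ValueError(f"{self.gene_id}: empty taxon set")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"{self.gene_id}: unequal sequence lengths {lengths}")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"{self.gene_id}: alignment length {length} not divisible by 3")
        bad = set("".join(self.sequences).upper()) - _NUCS
        if bad:
            raise ValueError(f"{self.gene_id}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequences[0])


@dataclasses.dataclass(frozen=True)
class ProteinAlignment:
    taxa: tuple[str, ...]
    sequences: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa/sequence count mismatch")
        if self.sequences and len({len(s) for s in self.sequences}) != 1:
            raise ValueError("unequal sequence lengths")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0


@dataclasses.dataclass(frozen=True)
class GeneBiasRecord:
    gene_id: str
    per_taxon_aminoGC: Mapping[str, float]
    aminoGC_sd: float
    dN_mean: float | None = None
    dS_mean: float | None = None


@dataclasses.dataclass(frozen=True)
class GeneDataset:
    label: str  # aminoGC_low | aminoGC_high | dN_low | dN_high
    size_k: int
    gene_ids: frozenset[str]


def amino_gc(aln: CodonAlignment) -> GeneBiasRecord:
    """Per-taxon G/C fraction at codon positions 1-2 and its across-taxa sd.

    Gaps and N are excluded from numerator and denominator.  Taxa with zero
    informative position-1/2 sites are excluded from the sd with a warning.
    The sd uses the sample (n-1) denominator.
    """
    fractions: dict[str, float] = {}
    for taxon, seq in zip(aln.taxa, aln.sequences):
        s = seq.upper()
        pos12 = s[0::3] + s[1::3]
        gc = pos12.count("G") + pos12.count("C")
        at = pos12.count("A") + pos12.count("T")
        if gc + at == 0:
            warnings.warn(
                f"{aln.gene_id}: taxon {taxon} has no informative position-1/2 "
                "sites; excluded from aminoGC sd"
            )
            continue
        fractions[taxon] = gc / (gc + at)
    values = np.array(list(fractions.values()))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return GeneBiasRecord(aln.gene_id, fractions, sd)


def rank_and_select(
    records: Sequence[GeneBiasRecord],
    k: int,
    criterion: str = "aminoGC",
    tail: str = "low",
) -> GeneDataset:
    """Select the k genes with smallest/largest aminoGC sd or dN.

    Records lacking a dN value are excluded (with a warning) when ranking by
    dN.  Ties at the k-th value break toward the lexicographically smaller
    gene_id.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if criterion not in ("aminoGC", "dN"):
        raise ValueError(f"unknown criterion {criterion!r}")
    if tail not in ("low", "high"):
        raise ValueError(f"unknown tail {tail!r}")
    if not records:
        raise ValueError("no records")

    def value(rec: GeneBiasRecord) -> float | None:
        return rec.aminoGC_sd if criterion == "aminoGC" else rec.dN_mean

    usable = [r for r in records if value(r) is not None]
    dropped = len(records) - len(usable)
    if dropped:
        warnings.warn(f"{dropped} records lack {criterion} values; excluded")
    if tail == "low":
        ordered = sorted(usable, key=lambda r: (value(r), r.gene_id))
    else:
        ordered = sorted(usable, key=lambda r: (-value(r), r.gene_id))
    chosen = ordered[:k]
    return GeneDataset(
        label=f"{criterion}_{tail}",
        size_k=k,
        gene_ids=frozenset(r.gene_id for r in chosen),
    )


def dataset_overlap(a: GeneDataset, b: GeneDataset) -> int:
    return len(a.gene_ids & b.gene_ids)


def _count_matrix(
    sequences: Sequence[str], site_index: Sequence[int]
) -> np.ndarray:
    """Taxa x 20 amino-acid count matrix over the given sites (gaps/X ignored)."""
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    counts = np.zeros((len(sequences), len(AMINO_ACIDS)), dtype=np.int64)
    for t, seq in enumerate(sequences):
        for j in site_index:
            i = aa_index.get(seq[j].upper())
            if i is not None:
                counts[t, i] += 1
    return counts


def _chi2_stat(counts: np.ndarray) -> tuple[float, float]:
    """Chi-square homogeneity statistic and p-value of a taxa x residue table.

    Empty rows/columns are dropped; a table with fewer than 2 non-empty rows
    or columns is perfectly homogeneous (statistic 0, p 1).
    """
    table = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 0.0, 1.0
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    p = float(stats.chi2.sf(stat, dof))
    return stat, p


def stationary_trim(
    concatenated: ProteinAlignment,
    alpha: float = 0.05,
    max_removed_fraction: float = 0.5,
) -> tuple[ProteinAlignment, list[int]]:
    """Greedily remove sites until amino-acid composition is homogeneous.

    While the chi-square test over the taxa x amino-acid count table rejects
    homogeneity at ``alpha`` and fewer than ``max_removed_fraction`` of sites
    have been removed, the single site whose removal most reduces the
    statistic is dropped (ties toward the smaller site index).  Returns the
    retained alignment and the 0-based removed site indices in removal order.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if concatenated.length == 0:
        raise ValueError("empty alignment")
    n_sites = concatenated.length
    retained = list(range(n_sites))
    removed: list[int] = []
    counts = _count_matrix(concatenated.sequences, retained)
    # per-site count columns, for incremental updates
    site_counts = {
        j: _count_matrix(concatenated.sequences, [j]) for j in range(n_sites)
    }
    max_removed = math.floor(max_removed_fraction * n_sites)
    while True:
        if not retained:
            raise RuntimeError(
                "all sites removed before compositional homogeneity was "
                f"reached (max_removed_fraction={max_removed_fraction})"
            )
        _, p = _chi2_stat(counts)
        if p >= alpha or len(removed) >= max_removed:
            break
        best_j = None
        best_stat = None
        for j in retained:
            stat_j, _ = _chi2_stat(counts - site_counts[j])
            if best_stat is None or stat_j < best_stat:
                best_stat, best_j = stat_j, j
        counts = counts - site_counts[best_j]
        retained.remove(best_j)
        removed.append(best_j)
    kept = ["".join(seq[j] for j in retained) for seq in concatenated.sequences]
    return ProteinAlignment(concatenated.taxa, tuple(kept)), removed


def concatenate_alignments(
    alignments: Mapping[str, ProteinAlignment]
) -> ProteinAlignment:
    """Concatenate per-gene protein alignments in lexicographic gene_id order.

    All alignments must share the same taxon set; taxa ordered as in the
    first gene (sorted by gene_id).
    """
    if not alignments:
        raise ValueError("no alignments to concatenate")
    gene_ids = sorted(alignments)
    taxa = alignments[gene_ids[0]].taxa
    taxon_set = set(taxa)
    parts: dict[str, list[str]] = {t: [] for t in taxa}
    for gid in gene_ids:
        aln = alignments[gid]
        if set(aln.taxa) != taxon_set:
            raise ValueError(f"gene {gid}: taxon set differs")
        lookup = dict(zip(aln.taxa, aln.sequences))
        for t in taxa:
            parts[t].append(lookup[t])
    return ProteinAlignment(taxa, tuple("".join(parts[t]) for t in taxa))
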