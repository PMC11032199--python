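"""aminoGC statistic, bias ranking, dataset overlap, stationary trimming."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stkflux.composition import (
    CodonAlignment,
    GeneBiasRecord,
    GeneDataset,
    ProteinAlignment,
    amino_gc,
    concatenate_alignments,
    dataset_overlap,
    rank_and_select,
    stationary_trim,
)


def make_records(values, criterion="aminoGC"):
    return [
        GeneBiasRecord(
            gene_id=gid,
            per_taxon_aminoGC={},
            aminoGC_sd=v if criterion == "aminoGC" else 0.0,
            dN_mean=v if criterion == "dN" else None,
        )
        for gid, v in values
    ]


class TestAminoGC:
    def test_identical_gc_rich_rows_give_fraction_one_sd_zero(self):
        aln = CodonAlignment("g", ("A", "B"), ("GGAGGA", "GGAGGA"))
        rec = amino_gc(aln)
        assert rec.per_taxon_aminoGC == {"A": 1.0, "B": 1.0}
        assert rec.aminoGC_sd == 0.0

    def test_no_gc_taxon_has_fraction_zero(self):
        aln = CodonAlignment("g", ("A",), ("ATAATA",))
        assert amino_gc(aln).per_taxon_aminoGC["A"] == 0.0

    def test_sd_is_sample_standard_deviation(self):
        # fractions 0.4 and 0.6 -> sqrt(((0.4-0.5)^2+(0.6-0.5)^2)/1)
        seq_04 = "ATA" * 3 + "GCA" * 2  # pos12 G/C fraction = 4/10
        seq_06 = "ATA" * 2 + "GCA" * 3  # 6/10
        aln = CodonAlignment("g", ("A", "B"), (seq_04, seq_06))
        rec = amino_gc(aln)
        assert rec.per_taxon_aminoGC["A"] == pytest.approx(0.4)
        assert rec.per_taxon_aminoGC["B"] == pytest.approx(0.6)
        assert rec.aminoGC_sd == pytest.approx(0.1414213562, abs=1e-9)

    def test_gaps_and_n_excluded(self):
        # codons GCA / -TA / NNG: informative pos-1/2 chars are G,C,T -> 2/3
        aln = CodonAlignment("g", ("A",), ("GCA-TANNG",))
        assert amino_gc(aln).per_taxon_aminoGC["A"] == pytest.approx(2 / 3)

    def test_all_gap_taxon_excluded_with_warning(self):
        aln = CodonAlignment("g", ("A", "B", "C"),
                             ("GGAGGA", "ATAATA", "--N--N"))
        with pytest.warns(UserWarning, match="excluded"):
            rec = amino_gc(aln)
        assert "C" not in rec.per_taxon_aminoGC
        assert rec.aminoGC_sd == pytest.approx(np.std([1.0, 0.0], ddof=1))

    def test_length_not_divisible_by_three_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            CodonAlignment("g", ("A",), ("GGAG",))

    def test_invariant_under_taxon_reordering(self):
        aln = CodonAlignment("g", ("A", "B", "C"),
                             ("GGAGGA", "ATAGCA", "GCTGCT"))
        rev = CodonAlignment("g", ("C", "B", "A"),
                             ("GCTGCT", "ATAGCA", "GGAGGA"))
        a, b = amino_gc(aln), amino_gc(rev)
        assert a.per_taxon_aminoGC == b.per_taxon_aminoGC
        assert a.aminoGC_sd == b.aminoGC_sd

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.data())
    def test_third_positions_never_enter_statistic(self, data):
        codons = data.draw(st.lists(
            st.tuples(st.sampled_from("ACGT"), st.sampled_from("ACGT"),
                      st.sampled_from("ACGT")),
            min_size=2, max_size=30))
        seq = "".join("".join(c) for c in codons)
        mutated = list(seq)
        for i in range(2, len(seq), 3):
            mutated[i] = data.draw(st.sampled_from("ACGT"))
        aln1 = CodonAlignment("g", ("A",), (seq,))
        aln2 = CodonAlignment("g", ("A",), ("".join(mutated),))
        assert (amino_gc(aln1).per_taxon_aminoGC
                == amino_gc(aln2).per_taxon_aminoGC)


class TestRankAndSelect:
    def test_smallest_selected(self):
        recs = make_records([("g1", 0.1), ("g2", 0.2), ("g3", 0.3)])
        ds = rank_and_select(recs, 1, "aminoGC", "low")
        assert ds.gene_ids == {"g1"}

    def test_tie_break_lexicographic(self):
        recs = make_records([("gB", 0.2), ("gA", 0.2), ("gC", 0.1)])
        ds = rank_and_select(recs, 2, "aminoGC", "low")
        assert ds.gene_ids == {"gC", "gA"}

    def test_low_and_high_disjoint_when_enough_genes(self, rng):
        recs = make_records([(f"g{i:03d}", float(v))
                             for i, v in enumerate(rng.random(114))])
        low = rank_and_select(recs, 25, "aminoGC", "low")
        high = rank_and_select(recs, 25, "aminoGC", "high")
        assert len(low.gene_ids) == len(high.gene_ids) == 25
        assert not (low.gene_ids & high.gene_ids)

    def test_records_without_dn_excluded_with_warning(self):
        recs = make_records([("g1", 0.5), ("g2", 0.1)], criterion="dN")
        recs.append(GeneBiasRecord("g3", {}, 0.0, dN_mean=None))
        with pytest.warns(UserWarning, match="lack dN"):
            ds = rank_and_select(recs, 2, "dN", "low")
        assert ds.gene_ids == {"g1", "g2"}

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            rank_and_select(make_records([("g", 0.1)]), 0)


class TestDatasetOverlap:
    def test_identical_and_disjoint(self):
        a = GeneDataset("aminoGC_low", 25, frozenset(f"g{i}" for i in range(25)))
        b = GeneDataset("dN_low", 25, frozenset(f"g{i}" for i in range(25)))
        c = GeneDataset("dN_low", 25, frozenset(f"h{i}" for i in range(25)))
        assert dataset_overlap(a, b) == 25
        assert dataset_overlap(a, c) == 0

    def test_correlated_criteria_overlap_beats_chance(self, rng):
        # aminoGC_sd and dN correlated at r ~ 0.8: the two "low" sets should
        # share far more genes than the hypergeometric expectation k^2/n.
        n, k = 114, 25
        x = rng.random(n)
        y = 0.8 * x + 0.6 * rng.random(n)
        recs = [
            GeneBiasRecord(f"g{i:03d}", {}, float(x[i]), dN_mean=float(y[i]))
            for i in range(n)
        ]
        low_gc = rank_and_select(recs, k, "aminoGC", "low")
        low_dn = rank_and_select(recs, k, "dN", "low")
        expected_by_chance = k * k / n  # ~5.5
        assert dataset_overlap(low_gc, low_dn) > expected_by_chance


class TestStationaryTrim:
    def test_identical_rows_remove_nothing(self):
        aln = ProteinAlignment(("a", "b", "c"), ("ACDEF",) * 3)
        trimmed, removed = stationary_trim(aln, alpha=0.05)
        assert removed == []
        assert trimmed.sequences == aln.sequences

    def test_tiny_alpha_never_rejects(self, rng):
        seqs = tuple("".join(rng.choice(list("ACDEFGHIKL"), size=30))
                     for _ in range(6))
        aln = ProteinAlignment(tuple("t%d" % i for i in range(6)), seqs)
        _, removed = stationary_trim(aln, alpha=1e-300)
        assert removed == []

    def test_heterogeneous_sites_removed_first(self):
        # 20 taxa; 10 homogeneous sites + 2 sites split W / D between two
        # halves of the taxa.  Exactly those 2 sites must go, smaller index
        # first (their leave-one-out statistics tie).  At this toy size a
        # composition test has almost no power (2 residues per taxon), so the
        # loop is driven with a near-1 alpha, i.e. near-exact homogeneity is
        # demanded; what is under test is the greedy site selection.
        n_taxa = 20
        rows = []
        for t in range(n_taxa):
            het = "W" if t < n_taxa // 2 else "D"
            site_chars = ["A"] * 3 + [het] + ["A"] * 5 + [het] + ["A"] * 2
            rows.append("".join(site_chars))
        aln = ProteinAlignment(tuple(f"t{t}" for t in range(n_taxa)), tuple(rows))
        assert aln.length == 12
        trimmed, removed = stationary_trim(aln, alpha=0.9995)
        assert removed == [3, 9]
        assert trimmed.length == 10

    def test_idempotent(self, rng):
        for _ in range(5):
            seqs = tuple("".join(rng.choice(list("ACDEFGHIKLMNPQ"), size=40))
                         for _ in range(8))
            aln = ProteinAlignment(tuple(f"t{i}" for i in range(8)), seqs)
            trimmed, _ = stationary_trim(aln, alpha=0.05, max_removed_fraction=0.9)
            again, removed2 = stationary_trim(trimmed, alpha=0.05,
                                              max_removed_fraction=0.9)
            assert removed2 == []
            assert again.sequences == trimmed.sequences

    def test_bad_alpha_rejected(self):
        aln = ProteinAlignment(("a",), ("ACD",))
        with pytest.raises(ValueError):
            stationary_trim(aln, alpha=1.5)


class TestConcatenate:
    def test_lexicographic_gene_order(self):
        a = ProteinAlignment(("t1", "t2"), ("AA", "CC"))
        b = ProteinAlignment(("t2", "t1"), ("DD", "EE"))
        cat = concatenate_alignments({"g2": b, "g1": a})
        assert cat.taxa == ("t1", "t2")
        assert cat.sequences == ("AAEE", "CCDD")

    def test_taxon_set_mismatch_rejected(self):
        a = ProteinAlignment(("t1", "t2"), ("AA", "CC"))
        b = ProteinAlignment(("t1", "t3"), ("DD", "EE"))
        with pytest.raises(ValueError, match="taxon set"):
            concatenate_alignments({"g1": a, "g2": b})
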