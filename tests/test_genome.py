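"""lncRNA positional classification and cis-neighbor queries."""

import numpy as np
import pytest

import _oracles as oracles
from cncnet.errors import DomainError
from cncnet.genome import (TranscriptRecord, cis_neighbors, classify_all,
                           classify_lncrna)


def _gene(gid, start, strand="+", chrom="chr1", exons=None):
    return TranscriptRecord(gid, gid, "mRNA", chrom, start, start + 20_000,
                            strand,
                            exons or ((start, start + 2000),
                                      (start + 18_000, start + 20_000)))


def _lnc(lid, start, end, strand="+", chrom="chr1"):
    return TranscriptRecord(lid, lid, "lncRNA", chrom, start, end, strand)


GENE = _gene("G1", 10_000)


@pytest.mark.parametrize("lnc,expected", [
    (_lnc("L", 11_000, 11_500, "+"), {"exon_overlapping"}),
    (_lnc("L", 15_000, 16_000, "+"), {"intron_overlapping"}),
    (_lnc("L", 11_000, 11_500, "-"), {"natural_antisense"}),
    (_lnc("L", 15_000, 16_000, "-"), {"intron_antisense"}),
    (_lnc("L", 9_000, 9_600, "-"), {"bidirectional"}),
    (_lnc("L", 900_000, 900_800, "+"), {"intergenic"}),
])
def test_six_category_rules(lnc, expected):
    call = classify_lncrna(lnc, [GENE])
    assert set(call.labels) == expected


def test_multi_label_crossover_and_primary_precedence():
    gene_b = TranscriptRecord("G2", "G2", "mRNA", "chr1", 5000, 45_000, "-",
                              ((5000, 7000), (43_000, 45_000)))
    call = classify_lncrna(_lnc("L", 11_000, 11_500, "+"), [GENE, gene_b])
    assert set(call.labels) == {"exon_overlapping", "intron_antisense"}
    assert call.primary == "exon_overlapping"


def test_empty_coding_list_is_intergenic():
    call = classify_lncrna(_lnc("L", 100, 900), [])
    assert set(call.labels) == {"intergenic"}


def test_intergenic_exclusive_and_venn_partition():
    lncs = [_lnc(f"L{i}", 100_000 * i + 50_000, 100_000 * i + 50_800)
            for i in range(5)]
    summary = classify_all(lncs, [GENE])
    assert summary.category_counts["intergenic"] == 5
    assert sum(summary.venn_counts.values()) == len(lncs)
    assert summary.percentages["intergenic"] == 100.0


def _random_records(rng, n_genes=6, n_lnc=4, span=4000):
    genes, lncs = [], []
    for i in range(n_genes):
        s = int(rng.integers(0, span))
        length = int(rng.integers(100, 800))
        strand = "+-"[rng.integers(2)]
        if rng.random() < 0.5 and length > 300:
            e1 = s + int(rng.integers(50, length // 3))
            i2 = s + int(rng.integers(length * 2 // 3, length - 20))
            exons = ((s, e1), (i2, s + length))
        else:
            exons = ((s, s + length),)
        genes.append(TranscriptRecord(f"G{i}", f"G{i}", "mRNA", "chr1", s,
                                      s + length, strand, exons))
    for i in range(n_lnc):
        s = int(rng.integers(0, span))
        length = int(rng.integers(50, 600))
        lncs.append(_lnc(f"L{i}", s, s + length, "+-"[rng.integers(2)]))
    return genes, lncs


def test_classification_matches_base_set_oracle():
    rng = np.random.default_rng(42)
    for _ in range(300):
        genes, lncs = _random_records(rng)
        summary = classify_all(lncs, genes, bidir_window_bp=200)
        for call, lnc in zip(summary.calls, lncs):
            assert set(call.labels) == oracles.classify_oracle(lnc, genes, 200)


def test_translation_invariance():
    rng = np.random.default_rng(7)
    genes, lncs = _random_records(rng)
    shift = 123_456

    def moved(r):
        return TranscriptRecord(r.id, r.gene_id, r.rna_type, r.chrom,
                                r.start + shift, r.end + shift, r.strand,
                                tuple((s + shift, e + shift)
                                      for s, e in r.exons), r.is_circular)
    for lnc in lncs:
        a = classify_lncrna(lnc, genes)
        b = classify_lncrna(moved(lnc), [moved(g) for g in genes])
        assert set(a.labels) == set(b.labels)


def test_strand_flip_swaps_sense_antisense():
    rng = np.random.default_rng(8)
    genes, lncs = _random_records(rng)
    swap = {"exon_overlapping": "natural_antisense",
            "natural_antisense": "exon_overlapping",
            "intron_overlapping": "intron_antisense",
            "intron_antisense": "intron_overlapping"}

    def flip(r):
        return TranscriptRecord(r.id, r.gene_id, r.rna_type, r.chrom, r.start,
                                r.end, "-" if r.strand == "+" else "+",
                                r.exons, r.is_circular)
    for lnc in lncs:
        # flipping both strands preserves the sense/antisense overlap labels
        # (divergent promoter pairs become convergent, so bidirectionality is
        # excluded from the comparison)
        both = classify_lncrna(flip(lnc), [flip(g) for g in genes])
        orig = classify_lncrna(lnc, genes)
        assert {l for l in both.labels if l in swap} == \
            {l for l in orig.labels if l in swap}
        # flipping one swaps overlap-derived labels (bidirectionality may
        # legitimately appear or vanish under a single flip, so compare the
        # overlap labels only)
        a = set(classify_lncrna(lnc, genes).labels)
        if a <= set(swap):
            one = set(classify_lncrna(flip(lnc), genes).labels)
            assert {lab for lab in one if lab in swap} == \
                {swap[lab] for lab in a}


def test_cis_window_arithmetic():
    lnc = _lnc("L", 1_000_000, 1_005_000)
    near = TranscriptRecord("G_near", "G_near", "mRNA", "chr1", 1_200_000,
                            1_210_000, "+")
    far = TranscriptRecord("G_far", "G_far", "mRNA", "chr1", 1_400_000,
                           1_410_000, "+")
    other = TranscriptRecord("G_chr2", "G_chr2", "mRNA", "chr2", 1_200_000,
                             1_210_000, "+")
    pairs = cis_neighbors(lnc, [near, far, other])
    assert [(p.gene_id, p.distance_bp) for p in pairs] == [("G_near", 195_000)]
    assert pairs[0].relative_position == "downstream"


def test_cis_boundary_is_strict():
    lnc = _lnc("L", 0, 1000)
    at_window = TranscriptRecord("G", "G", "mRNA", "chr1", 301_000, 302_000, "+")
    just_in = TranscriptRecord("H", "H", "mRNA", "chr1", 300_999, 302_000, "+")
    assert cis_neighbors(lnc, [at_window]) == []
    assert [p.gene_id for p in cis_neighbors(lnc, [just_in])] == ["H"]


def test_cis_matches_exhaustive_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        genes = []
        for i in range(12):
            s = int(rng.integers(0, 2_000_000))
            genes.append(TranscriptRecord(f"G{i}", f"G{i}", "mRNA",
                                          f"chr{1 + int(rng.integers(2))}",
                                          s, s + int(rng.integers(100, 50_000)),
                                          "+-"[rng.integers(2)]))
        s = int(rng.integers(0, 2_000_000))
        lnc = _lnc("L", s, s + int(rng.integers(100, 20_000)),
                   chrom=f"chr{1 + int(rng.integers(2))}")
        window = int(rng.integers(10_000, 600_000))
        got = [(p.gene_id, p.distance_bp)
               for p in cis_neighbors(lnc, genes, window)]
        assert got == oracles.cis_oracle(lnc, genes, window)


def test_transcript_record_validation():
    with pytest.raises(DomainError):
        TranscriptRecord("X", "X", "mRNA", "chr1", 10, 5, "+")
    with pytest.raises(DomainError):
        TranscriptRecord("X", "X", "mRNA", "chr1", 0, 100, "*")
    with pytest.raises(DomainError):
        TranscriptRecord("X", "X", "mRNA", "chr1", 0, 100, "+",
                         ((0, 50), (40, 100)))
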