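"""Gene-structure arithmetic, splicing, translation and regulatory scans."""

import numpy as np
import pytest

from fibroin.gene_model import (
    GeneStructure,
    extract_cds,
    find_palindromes,
    find_polya_signal,
    revcomp,
    scan_promoter_elements,
    splice_transcript,
    translate,
)
from fibroin.io_formats import FibroinError, NucSeq, SeqFeature


def _random_cds(rng, n_codons):
    """In-frame CDS with ATG start and no stop codons."""
    codons = ["ATG"]
    safe = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")]
    idx = rng.integers(0, len(safe), size=n_codons - 1)
    codons += [safe[i] for i in idx]
    return "".join(codons)


def build_two_exon_gene(rng, exon1_coding=42, cds_extra=8385, utr5=27, utr3=78, intron_len=131):
    """Assemble a two-exon gene with the given length plan and random content."""
    cds = _random_cds(rng, (exon1_coding + cds_extra) // 3)
    utr5_seq = "".join(rng.choice(list("ACGT"), size=utr5)) if utr5 else ""
    utr3_seq = "TAA" + "".join(rng.choice(list("ACGT"), size=utr3 - 3))
    intron = "GT" + "".join(rng.choice(list("AT"), size=intron_len - 4)) + "AG"
    exon1 = utr5_seq + cds[:exon1_coding]
    exon2 = cds[exon1_coding:] + utr3_seq
    gene = NucSeq(id="g", residues=exon1 + intron + exon2)
    gs = GeneStructure(
        gene=gene,
        exons=[
            SeqFeature("exon", 1, len(exon1), "+", "e1"),
            SeqFeature("exon", len(exon1) + intron_len + 1, len(gene), "+", "e2"),
        ],
        intron=SeqFeature("intron", len(exon1) + 1, len(exon1) + intron_len, "+", "i1"),
        utr5_len=utr5,
        utr3_len=utr3,
    )
    return gs, cds


class TestLengthArithmetic:
    def test_fibroin_length_plan(self, rng):
        """Exon 69 (27 UTR) + intron 131 + exon 8463 (8385 coding + 78 UTR)."""
        gs, cds = build_two_exon_gene(rng)
        assert [len(e) for e in gs.exons] == [69, 8463]
        assert len(splice_transcript(gs)) == 8532
        assert gs.cds_len == 8427
        assert gs.n_codons == 2809
        assert gs.atg_taa_span == 8561
        assert extract_cds(gs).residues == cds

    def test_single_exon_gene_transcript_equals_gene(self):
        gene = NucSeq(id="g", residues="ATGGCTGCATAA")
        gs = GeneStructure(
            gene=gene, exons=[SeqFeature("exon", 1, 12, "+", "e1")], utr5_len=0, utr3_len=3
        )
        assert splice_transcript(gs).residues == gene.residues
        assert extract_cds(gs).residues == "ATGGCTGCA"

    def test_three_exon_splice_matches_concatenation_oracle(self, rng):
        parts = ["".join(rng.choice(list("ACGT"), size=n)) for n in (30, 60, 33)]
        spacers = ["GTAG" * 3] * 2
        gene = NucSeq(id="g", residues=parts[0] + spacers[0] + parts[1] + spacers[1] + parts[2])
        starts = [1, 31 + 12, 31 + 12 + 60 + 12]
        exons = [
            SeqFeature("exon", s, s + len(p) - 1, "+", f"e{i}")
            for i, (s, p) in enumerate(zip(starts, parts))
        ]
        gs = GeneStructure(gene=gene, exons=exons, utr5_len=0, utr3_len=3)
        assert splice_transcript(gs).residues == "".join(parts)  # direct concatenation

    def test_overlapping_exons_rejected(self):
        gene = NucSeq(id="g", residues="A" * 50)
        with pytest.raises(FibroinError, match="overlap"):
            GeneStructure(
                gene=gene,
                exons=[SeqFeature("exon", 1, 20, "+", "a"), SeqFeature("exon", 15, 40, "+", "b")],
                utr5_len=0,
                utr3_len=3,
            )

    def test_cds_not_multiple_of_three_rejected(self):
        gene = NucSeq(id="g", residues="ATGGCTGCTAA")  # 11 nt, utr3 3 -> cds 8
        with pytest.raises(FibroinError, match="multiple of 3"):
            GeneStructure(
                gene=gene, exons=[SeqFeature("exon", 1, 11, "+", "e")], utr5_len=0, utr3_len=3
            )


class TestTranslate:
    def test_basic(self):
        assert translate("ATGGCTGCA") == "MAA"

    def test_internal_stop_rejected(self):
        with pytest.raises(FibroinError, match="internal stop"):
            translate("ATGTAAGCA")

    def test_terminal_stop_dropped(self):
        assert translate("ATGGCTTAA") == "MA"

    def test_ambiguous_codon_rejected(self):
        with pytest.raises(FibroinError):
            translate("ATGGCN")

    def test_random_codons_match_lookup_table_oracle(self, rng):
        from Bio.Data.CodonTable import standard_dna_table

        cds = _random_cds(rng, 300)
        oracle = "".join(
            standard_dna_table.forward_table[cds[i : i + 3]] for i in range(0, len(cds), 3)
        )
        assert translate(cds) == oracle


class TestPromoterScan:
    def test_planted_tata_at_minus_25(self, rng):
        bg = "".join(rng.choice(list("CG"), size=100))
        upstream = bg[:-25] + "TATAAA" + bg[-19:]
        hits = scan_promoter_elements(upstream)
        assert ("TATA", -25) in [(h.element, h.offset) for h in hits]

    def test_all_g_upstream_is_empty(self):
        assert scan_promoter_elements("G" * 80) == []

    def test_offsets_invariant_under_5prime_padding(self, rng):
        bg = "".join(rng.choice(list("CG"), size=60))
        upstream = bg[:-30] + "CCAAT" + bg[-25:]
        base = {(h.element, h.offset) for h in scan_promoter_elements(upstream)}
        padded = {(h.element, h.offset) for h in scan_promoter_elements("G" * 40 + upstream)}
        assert base <= padded

    def test_planted_elements_recovered_across_random_promoters(self, rng):
        for _ in range(50):
            bg = list("".join(rng.choice(list("CG"), size=250)))
            offsets = {"TATA": -25, "CAAT": -224, "SGF": -137}
            planted = {"TATA": "TATAAA", "CAAT": "CCAAT", "SGF": "TGTTT"}
            for el, off in offsets.items():
                bg[250 + off : 250 + off + len(planted[el])] = planted[el]
            hits = {(h.element, h.offset) for h in scan_promoter_elements("".join(bg))}
            assert {(el, off) for el, off in offsets.items()} <= hits


class TestPolyASignal:
    def test_planted_56_bases_downstream(self):
        assert find_polya_signal("T" * 56 + "AATAAA" + "GC") == 56

    def test_absent_returns_none(self):
        assert find_polya_signal("GCGCGCGC") is None

    def test_matches_naive_scan_oracle(self, rng):
        for _ in range(30):
            s = "".join(rng.choice(list("ACGT"), size=120))
            naive = next((i for i in range(len(s) - 5) if s[i : i + 6] == "AATAAA"), None)
            assert find_polya_signal(s) == naive


def _palindrome_oracle(s, min_len):
    """All maximal reverse-complement palindromic spans, by exhaustive check."""
    spans = set()
    n = len(s)
    for i in range(n):
        for j in range(i + 1, n, 2):  # even length only
            sub = s[i : j + 1]
            if sub != revcomp(sub):
                continue
            extendable = (
                i > 0 and j + 1 < n and s[i - 1 : j + 2] == revcomp(s[i - 1 : j + 2])
            )
            if not extendable and len(sub) >= min_len:
                spans.add((i + 1, j + 1))
    return spans


class TestPalindromes:
    def test_restriction_site_is_palindromic(self):
        assert find_palindromes("GAATTC", 6) == [(1, 6)]

    def test_homopolymer_has_none(self):
        assert find_palindromes("AAAAAA", 4) == []

    def test_min_len_must_be_even(self):
        with pytest.raises(FibroinError):
            find_palindromes("GAATTC", 5)

    def test_random_sequence_matches_brute_force(self, rng):
        s = "".join(rng.choice(list("ACGT"), size=1000))
        assert set(find_palindromes(s, 6)) == _palindrome_oracle(s, 6)


class TestOnGeneratorOutput:
    def test_extract_cds_recovers_planted_cds(self, ground_truth, gene_structure):
        cds = extract_cds(gene_structure)
        assert translate(cds) == ground_truth.protein

    def test_planted_promoter_elements_recovered(self, ground_truth):
        up_len = ground_truth.spec.upstream_len
        hits = {(h.element, h.offset) for h in
                scan_promoter_elements(ground_truth.gene.residues[:up_len])}
        spec = ground_truth.spec
        assert {("TATA", spec.tata_offset), ("CAAT", spec.caat_offset),
                ("SGF", spec.sgf_offset)} <= hits

    def test_planted_polya_signal_offset(self, ground_truth):
        utr3 = next(f for f in ground_truth.features if f.kind == "utr3")
        after_stop = ground_truth.gene.residues[utr3.start + 2 :]
        assert find_polya_signal(after_stop) == ground_truth.spec.polya_offset

    def test_intron_contains_palindromes_checkable(self, ground_truth):
        intron = next(f for f in ground_truth.features if f.kind == "intron")
        seq = ground_truth.gene.slice(intron.start, intron.end)
        spans = find_palindromes(seq, 4)
        assert set(find_palindromes(seq, 4)) == _palindrome_oracle(seq, 4)
        assert all(1 <= a <= b <= len(seq) for a, b in spans)
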