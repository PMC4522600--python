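"""Gene-structure model: splicing, CDS extraction, translation, regulatory scans.

The length bookkeeping follows the convention of saturniid H-fibroin gene
records: the stop codon is the first codon of the 3' UTR, so the CDS excludes
it. Under that convention the arithmetic identity

    utr5_len + cds_len + utr3_len = transcript length

holds (the stop's three bases are counted inside the 3' UTR), and the ATG-TAA
genomic span is exon1-coding + intron + exon2-coding + 3.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .io_formats import FibroinError, NucSeq, SeqFeature

#: IUPAC ambiguity codes for motif patterns.
IUPAC_DNA = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_PROMOTER_MOTIFS = {"TATA": "TATAWA", "CAAT": "CCAAT", "SGF": "TGTTT"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def iupac_regex(pattern: str) -> re.Pattern:
    """Compile an IUPAC DNA pattern into a regular expression."""
    try:
        body = "".join(
            ch if len(IUPAC_DNA[ch]) == 1 else "[" + IUPAC_DNA[ch] + "]"
            for ch in pattern.upper()
        )
    except KeyError as e:
        raise FibroinError(f"invalid IUPAC code {e.args[0]!r} in pattern {pattern!r}") from e
    return re.compile(body)


def revcomp(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class GeneStructure:
    """Exon/intron/UTR coordinate model over a gene-scale :class:`NucSeq`.

    ``exons`` are coordinates on ``gene``; ``tss`` is the 1-based position of
    the transcription start (+1), which must be the first base of exon 1.
    """

    gene: NucSeq
    exons: list[SeqFeature]
    utr5_len: int
    utr3_len: int
    intron: SeqFeature | None = None
    tss: int | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise FibroinError("gene structure needs at least one exon")
        self.exons = sorted(self.exons, key=lambda f: f.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise FibroinError(f"exons overlap: {a.start}..{a.end} and {b.start}..{b.end}")
        if self.exons[-1].end > len(self.gene):
            raise FibroinError("exon extends beyond gene sequence")
        if self.tss is None:
            self.tss = self.exons[0].start
        if self.utr5_len >= len(self.exons[0]):
            raise FibroinError(
                f"5' UTR of {self.utr5_len} nt must be shorter than exon 1 ({len(self.exons[0])} nt)"
            )
        if self.utr3_len < 3:
            raise FibroinError("3' UTR must contain at least the stop codon (3 nt)")
        cds_len = self.cds_len
        if cds_len <= 0 or cds_len % 3 != 0:
            raise FibroinError(
                f"CDS length {cds_len} is not a positive multiple of 3 "
                f"(spliced {self.spliced_len}, utr5 {self.utr5_len}, utr3 {self.utr3_len})"
            )
        # arithmetic identity under the stop-in-3'UTR convention
        assert self.utr5_len + cds_len + 3 + self.utr3_len - 3 == self.spliced_len
        if self.intron is not None:
            iseq = self.gene.slice(self.intron.start, self.intron.end)
            if not (iseq.startswith("GT") and iseq.endswith("AG")):
                warnings.warn(
                    "intron does not have canonical GT...AG boundaries", stacklevel=2
                )

    @property
    def spliced_len(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def cds_len(self) -> int:
        return self.spliced_len - self.utr5_len - self.utr3_len

    @property
    def n_codons(self) -> int:
        return self.cds_len // 3

    @property
    def atg_taa_span(self) -> int:
        """Genomic ATG-TAA span in bp: coding exon bases + introns + the stop codon."""
        first = self.exons[0].start + self.utr5_len
        # stop codon = first 3 bases of the 3' UTR, on the last exon
        last = self.exons[-1].end - self.utr3_len + 3
        return last - first + 1


def splice_transcript(gs: GeneStructure) -> NucSeq:
    """Concatenate exon sequences in order (the mature transcript, DNA alphabet)."""
    seq = "".join(gs.gene.slice(e.start, e.end) for e in gs.exons)
    return NucSeq(id=gs.gene.id + "_mRNA", residues=seq, description="spliced transcript")


def extract_cds(gs: GeneStructure, require_atg: bool = False) -> NucSeq:
    """Transcript minus the UTRs; starts at ATG, excludes the stop codon."""
    tx = splice_transcript(gs)
    cds = tx.residues[gs.utr5_len : len(tx.residues) - gs.utr3_len]
    if not cds.startswith("ATG"):
        msg = f"CDS does not start with ATG (got {cds[:3]!r})"
        if require_atg:
            raise FibroinError(msg)
        warnings.warn(msg, stacklevel=2)
    if len(cds) % 3 != 0:
        raise FibroinError(f"CDS length {len(cds)} not a multiple of 3")
    return NucSeq(id=gs.gene.id + "_CDS", residues=cds, description="coding sequence, stop excluded")


def translate(cds: NucSeq | str) -> str:
    """Conceptual translation under the standard genetic code.

    The input must be in frame with no internal stop; ambiguous (non-ACGT)
    codons are rejected.
    """
    seq = cds.residues if isinstance(cds, NucSeq) else cds.upper()
    if len(seq) % 3 != 0:
        raise FibroinError(f"CDS length {len(seq)} not a multiple of 3")
    bad = set(seq) - set("ACGT")
    if bad:
        raise FibroinError(f"ambiguous nucleotides in CDS: {sorted(bad)}")
    protein = str(Seq(seq).translate(table=1))
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise FibroinError(f"internal stop codon at codon {protein.index('*') + 1}")
    return protein


@dataclass
class PromoterHit:
    """A regulatory-element match upstream of +1 (offset of its 5'-most base)."""

    element: str
    offset: int
    matched: str

    def __post_init__(self) -> None:
        if self.offset >= 0:
            raise FibroinError("upstream promoter hits must have negative offsets")


def scan_promoter_elements(
    upstream: NucSeq | str,
    motifs: dict[str, str] | None = None,
) -> list[PromoterHit]:
    """Scan the region 5' of +1 for promoter elements (TATA/CAAT/SGF by default).

    ``upstream`` is the coding-strand sequence whose last base sits at -1
    (there is no position 0). Offsets are those of each match's 5'-most base.
    """
    seq = upstream.residues if isinstance(upstream, NucSeq) else upstream.upper()
    motifs = motifs or DEFAULT_PROMOTER_MOTIFS
    hits = []
    for name, pattern in motifs.items():
        rx = iupac_regex(pattern)
        for m in rx.finditer(seq):
            hits.append(PromoterHit(element=name, offset=m.start() - len(seq), matched=m.group()))
    hits.sort(key=lambda h: (h.offset, h.element))
    return hits


def find_polya_signal(seq_after_stop: NucSeq | str, signal: str = "AATAAA") -> int | None:
    """Offset (bases after the stop codon) of the first polyadenylation signal.

    Returns ``None`` when absent. An offset of 56 means 56 bases separate the
    stop codon from the signal's first base.
    """
    seq = seq_after_stop.residues if isinstance(seq_after_stop, NucSeq) else seq_after_stop.upper()
    idx = seq.find(signal)
    return idx if idx >= 0 else None


def find_palindromes(seq: NucSeq | str, min_len: int = 6) -> list[tuple[int, int]]:
    """Maximal reverse-complement palindromic spans of length >= ``min_len``.

    Spans are 1-based inclusive. A palindrome here is a substring equal to its
    own reverse complement (necessarily even-length); maximal means it cannot
    be symmetrically extended. Only unambiguous bases pair.
    """
    if min_len < 4 or min_len % 2 != 0:
        raise FibroinError("min_len must be an even number >= 4")
    s = seq.residues if isinstance(seq, NucSeq) else seq.upper()
    n = len(s)
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    spans = []
    for center in range(1, n):  # palindrome occupies [i..center-1][center..j]
        i, j = center - 1, center
        if s[j] != comp.get(s[i]):
            continue
        while i - 1 >= 0 and j + 1 < n and s[j + 1] == comp.get(s[i - 1]):
            i -= 1
            j += 1
        if j - i + 1 >= min_len:
            spans.append((i + 1, j + 1))
    return spans


def gene_check_report(gs: GeneStructure, repeat_region_len: int | None = None) -> dict:
    """Length-arithmetic consistency report for an annotated gene structure."""
    tx = splice_transcript(gs)
    cds = extract_cds(gs)
    report = {
        "gene_id": gs.gene.id,
        "exon_lengths_nt": [len(e) for e in gs.exons],
        "intron_length_nt": len(gs.intron) if gs.intron else 0,
        "utr5_len_nt": gs.utr5_len,
        "utr3_len_nt": gs.utr3_len,
        "transcript_length_nt": len(tx),
        "cds_length_nt": len(cds),
        "n_codons": len(cds) // 3,
        "atg_taa_span_bp": gs.atg_taa_span,
        "identity_holds": gs.utr5_len + len(cds) + gs.utr3_len == len(tx),
    }
    if repeat_region_len is not None:
        report["repeat_region_nt"] = repeat_region_len
        report["repetitive_fraction_pct"] = round(100.0 * repeat_region_len / len(cds), 1)
    return report
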