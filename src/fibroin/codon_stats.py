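"""Codon-level statistics of the fibroin CDS.

Isocodon usage is reported per amino acid in the RNA alphabet (GCA/GGU/UCA),
as codon-bias tables for silk genes conventionally are; all internal
bookkeeping stays in DNA. Homocodon runs are counted in frame: the biology
(polyalanine tract stability) concerns codons, not raw trinucleotides.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .io_formats import FibroinError, NucSeq

#: amino acid -> tuple of DNA codons, standard genetic code
CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] += (_codon,)

STOP_CODONS = frozenset(standard_dna_table.stop_codons)


def _codons_of(cds: NucSeq | str) -> list[str]:
    seq = cds.residues if isinstance(cds, NucSeq) else cds.upper()
    if not seq:
        raise FibroinError("empty CDS")
    if len(seq) % 3 != 0:
        raise FibroinError(f"CDS length {len(seq)} not a multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    for i, c in enumerate(codons, start=1):
        if c in STOP_CODONS:
            raise FibroinError(f"internal stop codon {c} at codon {i}")
        if c not in standard_dna_table.forward_table:
            raise FibroinError(f"unrecognised codon {c!r} at codon {i}")
    return codons


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


@dataclass
class CodonUsageTable:
    """Per-amino-acid isocodon counts and within-amino-acid percentages.

    ``counts`` maps amino acid -> {RNA codon -> count}. Counts may be
    fractional when a table is reconstructed from published percentages.
    """

    counts: dict[str, dict[str, float]]
    total_codons: float

    def percent(self, aa: str, codon: str) -> float:
        aa_total = sum(self.counts[aa].values())
        return 100.0 * self.counts[aa][codon] / aa_total if aa_total else 0.0

    def preferred_codon(self, aa: str) -> str:
        """Most frequent isocodon; ties break lexicographically."""
        if aa not in self.counts or not sum(self.counts[aa].values()):
            raise FibroinError(f"amino acid {aa!r} absent from usage table")
        return max(sorted(self.counts[aa]), key=lambda c: self.counts[aa][c])

    @classmethod
    def from_cds(cls, cds: NucSeq | str) -> "CodonUsageTable":
        codons = _codons_of(cds)
        tallies = Counter(codons)
        counts: dict[str, dict[str, float]] = {}
        for aa, aa_codons in CODONS_BY_AA.items():
            counts[aa] = {to_rna(c): float(tallies.get(c, 0)) for c in aa_codons}
        return cls(counts=counts, total_codons=float(len(codons)))

    @classmethod
    def from_percentages(
        cls, percentages: dict[str, dict[str, float]], aa_totals: dict[str, float]
    ) -> "CodonUsageTable":
        """Reconstruct (fractional) counts from published per-aa isocodon
        percentages and per-aa residue totals."""
        counts = {
            aa: {codon: pct / 100.0 * aa_totals[aa] for codon, pct in table.items()}
            for aa, table in percentages.items()
        }
        total = sum(aa_totals.values())
        return cls(counts=counts, total_codons=float(total))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for aa in sorted(self.counts):
            for codon in sorted(self.counts[aa]):
                rows.append(
                    {
                        "aa": aa,
                        "codon": codon,
                        "count": self.counts[aa][codon],
                        "percent": round(self.percent(aa, codon), 1),
                    }
                )
        return pd.DataFrame(rows, columns=["aa", "codon", "count", "percent"])


def codon_usage(cds: NucSeq | str) -> CodonUsageTable:
    """Isocodon usage table of an in-frame CDS (stop codon excluded upstream)."""
    return CodonUsageTable.from_cds(cds)


@dataclass
class PositionalBias:
    """Base fractions at each codon position (1..3)."""

    fractions: list[dict[str, float]]

    def fraction(self, position: int, base: str) -> float:
        return self.fractions[position - 1].get(base, 0.0)

    @property
    def au3(self) -> float:
        """Combined A+U fraction at the third codon position."""
        return self.fraction(3, "A") + self.fraction(3, "T")


def positional_base_fractions(cds: NucSeq | str) -> PositionalBias:
    codons = _codons_of(cds)
    n = len(codons)
    fractions = []
    for pos in range(3):
        tallies = Counter(c[pos] for c in codons)
        fractions.append({b: tallies.get(b, 0) / n for b in "ACGT"})
    return PositionalBias(fractions=fractions)


def gc_content(seq: NucSeq | str, which: str = "all") -> float:
    """GC fraction of a sequence, over all bases or third codon positions only."""
    s = seq.residues if isinstance(seq, NucSeq) else seq.upper()
    if not s:
        raise FibroinError("empty sequence")
    if which == "all":
        sub = s
    elif which == "gc3":
        if len(s) % 3 != 0:
            raise FibroinError("gc3 requires an in-frame CDS")
        sub = s[2::3]
    else:
        raise FibroinError(f"unknown mode {which!r}")
    return (sub.count("G") + sub.count("C")) / len(sub)


def longest_homocodon_run(cds: NucSeq | str, codon: str) -> int:
    """Longest run of consecutive in-frame occurrences of one codon."""
    if len(codon) != 3:
        raise FibroinError("codon must have length 3")
    codon = codon.upper()
    seq = cds.residues if isinstance(cds, NucSeq) else cds.upper()
    if len(seq) % 3 != 0:
        raise FibroinError(f"CDS length {len(seq)} not a multiple of 3")
    best = run = 0
    for i in range(0, len(seq), 3):
        if seq[i : i + 3] == codon:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def combined_top_isocodon_fraction(
    usage: CodonUsageTable, aas: tuple[str, ...] = ("A", "G", "S")
) -> float:
    """Fraction of all codons taken by the preferred isocodon of each given aa.

    For this fibroin the preferred codons of Ala/Gly/Ser (GCA, GGU, UCA)
    dominate the coding sequence.
    """
    total = 0.0
    for aa in aas:
        top = usage.preferred_codon(aa)
        total += usage.counts[aa][top]
    return total / usage.total_codons


@dataclass
class CpGIsland:
    start: int  # 1-based inclusive nucleotide coordinates
    end: int
    gc: float
    obs_exp_cpg: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def _window_stats(s: str, start0: int, length: int) -> tuple[float, float]:
    win = s[start0 : start0 + length]
    g, c = win.count("G"), win.count("C")
    cpg = win.count("CG")
    gc = (g + c) / length
    oe = (cpg * length) / (c * g) if c and g else 0.0
    return gc, oe


def cpg_islands(
    seq: NucSeq | str,
    window: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
) -> list[CpGIsland]:
    """Gardiner-Garden-style sliding-window CpG-island screen.

    Every window (step 1) with GC >= ``gc_min`` and observed/expected CpG >=
    ``oe_min`` qualifies; overlapping or abutting qualifying windows are merged
    and each merged island is re-scored over its full span.
    """
    s = seq.residues if isinstance(seq, NucSeq) else seq.upper()
    if len(s) < window:
        raise FibroinError(f"sequence of {len(s)} nt shorter than window {window}")
    qualifying: list[tuple[int, int]] = []
    for i in range(len(s) - window + 1):
        gc, oe = _window_stats(s, i, window)
        if gc >= gc_min and oe >= oe_min:
            if qualifying and i <= qualifying[-1][1] + 1:
                qualifying[-1] = (qualifying[-1][0], i + window - 1)
            else:
                qualifying.append((i, i + window - 1))
    islands = []
    for start0, end0 in qualifying:
        gc, oe = _window_stats(s, start0, end0 - start0 + 1)
        islands.append(CpGIsland(start=start0 + 1, end=end0 + 1, gc=gc, obs_exp_cpg=oe))
    return islands
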