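"""Synthetic fibroin-like gene generator with full ground truth.

Emulates the architecture of a saturniid H-fibroin gene — promoter with
TATA/CAAT/silk-gland-factor elements, a two-exon gene with a short AT-rich
intron, short UTRs, and a CDS whose protein is [signal][N-amorphous]
[hexaserine linker][alternating A / non-A motif core][C-amorphous] — under a
biased isocodon table, so every pipeline stage can be tested against planted
truth without any download.

The default motif templates are synthetic: they are built to match the
published per-class composition statistics (proximal GSGAGG anchors, Gly/Tyr
rich G-motifs, ~27% Arg R-motifs), not copied from any deposited sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .architecture import MotifSpan
from .gene_model import GeneStructure
from .io_formats import FibroinError, NucSeq, SeqFeature

#: Published-style isocodon percentages for the three major residues of this
#: fibroin (DNA alphabet); all other amino acids default to uniform usage.
AAFHC_ISOCODON_PCT: dict[str, dict[str, float]] = {
    "A": {"GCA": 67.3, "GCC": 3.4, "GCG": 14.0, "GCT": 15.3},
    "G": {"GGA": 30.3, "GGC": 27.5, "GGG": 0.6, "GGT": 41.6},
    "S": {"AGC": 1.0, "AGT": 9.0, "TCA": 69.7, "TCC": 7.0, "TCG": 6.6, "TCT": 6.6},
}

#: Synthetic motif templates (see module docstring). G templates begin with
#: the GSGAGG anchor and avoid terminal Ala so planted A-runs stay maximal.
DEFAULT_TEMPLATES: dict[str, str] = {
    "Ga": "GSGAGGYGYGAGYGSGAG",  # 18 aa
    "Gb": "GSGAGGYGYGSGYGAGYGAG",  # 20 aa
    "Gc": "GSGAGGYGYGSRGDGYGAGSGAG",  # 23 aa, carries the RGD tripeptide
    "R": "RAGYRAGSRAYGRAGSRAYGR",  # 21 aa, 6/21 ~ 29% Arg, ~10% Ser
}

DEFAULT_MOTIF_PLAN: dict[str, int] = {"R": 17, "Ga": 15, "Gb": 46, "Gc": 5}

_SIGNAL_TEMPLATE = "MRVTALVILSAALQYATA"  # 18 aa, Met-initial, hydrophobic-rich

# residue pools for the amorphous regions (no Ala/Cys: Ala runs must stay
# unique to A-motifs and Cys unique to the C-terminus)
_NTERM_ALPHABET = "GSTNQDEYPVRH"
_NTERM_WEIGHTS = (0.14, 0.14, 0.08, 0.05, 0.06, 0.10, 0.07, 0.08, 0.06, 0.08, 0.08, 0.06)
_CTERM_ALPHABET = "GSTNQDEYPVKRH"
_CTERM_WEIGHTS = (0.10, 0.16, 0.07, 0.05, 0.06, 0.04, 0.04, 0.08, 0.05, 0.05, 0.12, 0.12, 0.06)


def default_isocodon_freqs() -> dict[str, dict[str, float]]:
    """Per-amino-acid codon sampling frequencies (normalised to sum to 1)."""
    from .codon_stats import CODONS_BY_AA

    freqs: dict[str, dict[str, float]] = {}
    for aa, codons in CODONS_BY_AA.items():
        if aa in AAFHC_ISOCODON_PCT:
            table = AAFHC_ISOCODON_PCT[aa]
            total = sum(table.values())
            freqs[aa] = {c: v / total for c, v in table.items()}
        else:
            freqs[aa] = {c: 1.0 / len(codons) for c in codons}
    return freqs


@dataclass
class FibroinSpec:
    """Study conditions for one synthetic fibroin gene."""

    motif_plan: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_MOTIF_PLAN))
    motif_templates: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    a_len_range: tuple[int, int] = (5, 15)
    template_mutation_rate: float = 0.0
    nterm_len: int = 127  # includes the signal peptide
    signal_len: int = 18
    linker: str = "SSSSSS"
    cterm_len: int = 34
    cterm_n_cys: int = 3
    isocodon_freqs: dict[str, dict[str, float]] | None = None
    intron_len: int = 131
    intron_gc: float = 0.21
    utr5_len: int = 27
    utr3_len: int = 78  # stop-initial
    exon1_coding_len: int = 42
    polya_offset: int = 56  # bases between stop codon and AATAAA
    upstream_len: int = 250
    tata_offset: int = -25
    caat_offset: int = -224
    sgf_offset: int = -137
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.linker) != {"S"}:
            raise FibroinError("linker must be all-serine")
        for name in ("nterm_len", "cterm_len", "intron_len", "utr5_len", "utr3_len"):
            if getattr(self, name) <= 0:
                raise FibroinError(f"{name} must be positive")
        if self.utr3_len < 3 + self.polya_offset + 6:
            raise FibroinError("3' UTR too short to hold the polyadenylation signal")
        if self.isocodon_freqs is None:
            self.isocodon_freqs = default_isocodon_freqs()
        for aa, table in self.isocodon_freqs.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-6:
                raise FibroinError(f"isocodon frequencies for {aa!r} sum to {total}, not 1")
        for cls, count in self.motif_plan.items():
            if cls not in self.motif_templates:
                raise FibroinError(f"motif class {cls!r} has no template")
            if count < 0:
                raise FibroinError("motif counts must be non-negative")


@dataclass
class GroundTruth:
    """Everything the generator planted, for round-trip testing."""

    protein: str
    spans: list[MotifSpan]
    gene: NucSeq
    features: list[SeqFeature]
    codon_draws: dict[str, Counter]
    spec: FibroinSpec

    def gene_structure(self) -> GeneStructure:
        exons = [f for f in self.features if f.kind == "exon"]
        introns = [f for f in self.features if f.kind == "intron"]
        return GeneStructure(
            gene=self.gene,
            exons=exons,
            intron=introns[0] if introns else None,
            utr5_len=self.spec.utr5_len,
            utr3_len=self.spec.utr3_len,
        )


def reverse_translate(
    protein: str,
    isocodon_freqs: dict[str, dict[str, float]],
    rng: np.random.Generator,
) -> tuple[str, dict[str, Counter]]:
    """Sample a CDS encoding ``protein`` under per-amino-acid codon frequencies.

    One independent multinomial draw per residue, in sequence order; returns
    the DNA CDS and the realised per-amino-acid codon tallies.
    """
    codons: list[str] = []
    draws: dict[str, Counter] = {}
    for aa in protein:
        if aa not in isocodon_freqs:
            raise FibroinError(f"no codon frequencies for residue {aa!r}")
        table = isocodon_freqs[aa]
        keys = sorted(table)
        probs = np.array([table[k] for k in keys])
        codon = keys[rng.choice(len(keys), p=probs / probs.sum())]
        codons.append(codon)
        draws.setdefault(aa, Counter())[codon] += 1
    return "".join(codons), draws


def _mutate_template(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-residue substitution; never substitutes *to* Ala, so mutation cannot
    create or extend a polyalanine run anywhere in the core."""
    if rate <= 0:
        return seq
    alphabet = "GSTNQDEYPVRHKFLM"
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [c for c in alphabet if c != out[i]]
            out[i] = choices[rng.choice(len(choices))]
    return "".join(out)


def _break_runs(residues: list[str], max_a: int, max_s: int) -> None:
    """Cap A and S run lengths in place so amorphous regions cannot mimic
    A-motifs or the hexaserine linker."""
    for ch, cap in (("A", max_a), ("S", max_s)):
        run = 0
        for i, r in enumerate(residues):
            if r == ch:
                run += 1
                if run >= cap:
                    residues[i] = "T"
                    run = 0
            else:
                run = 0


def _random_region(
    rng: np.random.Generator, length: int, alphabet: str, weights: tuple[float, ...]
) -> list[str]:
    probs = np.array(weights) / sum(weights)
    idx = rng.choice(len(alphabet), size=length, p=probs)
    return [alphabet[i] for i in idx]


def _random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=probs)
    return "".join("GCAT"[i] for i in idx)


def _make_intron(rng: np.random.Generator, length: int, gc_target: float) -> str:
    """AT-rich intron with canonical GT...AG ends and an exact GC count."""
    if length < 8:
        raise FibroinError("intron too short")
    n_gc = round(gc_target * length)
    interior = length - 4
    n_gc_interior = max(0, n_gc - 2)  # GT...AG already contribute one G each
    bases = ["G" if rng.random() < 0.5 else "C" for _ in range(n_gc_interior)]
    bases += ["A" if rng.random() < 0.5 else "T" for _ in range(interior - n_gc_interior)]
    rng.shuffle(bases)
    return "GT" + "".join(bases) + "AG"


def generate(spec: FibroinSpec | None = None) -> GroundTruth:
    """Generate one fibroin-like gene with planted ground truth (seed-determined)."""
    spec = spec or FibroinSpec()
    rng = np.random.default_rng(spec.seed)

    # --- protein ----------------------------------------------------------
    signal = _SIGNAL_TEMPLATE[: spec.signal_len].ljust(spec.signal_len, "L")
    nbody = _random_region(
        rng, spec.nterm_len - spec.signal_len, _NTERM_ALPHABET, _NTERM_WEIGHTS
    )
    _break_runs(nbody, max_a=3, max_s=len(spec.linker) - 1)
    nbody = "".join(nbody)

    order = [cls for cls, n in sorted(spec.motif_plan.items()) for _ in range(n)]
    rng.shuffle(order)
    lo, hi = spec.a_len_range
    core_parts: list[tuple[str, str]] = []  # (class, sequence)
    core_parts.append(("A", "A" * int(rng.integers(lo, hi + 1))))
    for cls in order:
        motif = _mutate_template(spec.motif_templates[cls], spec.template_mutation_rate, rng)
        core_parts.append((cls, motif))
        core_parts.append(("A", "A" * int(rng.integers(lo, hi + 1))))
    core = "".join(seq for _, seq in core_parts)

    cbody = _random_region(rng, spec.cterm_len, _CTERM_ALPHABET, _CTERM_WEIGHTS)
    _break_runs(cbody, max_a=3, max_s=len(spec.linker) - 1)
    if spec.cterm_n_cys > 0:
        cys_at = np.linspace(2, spec.cterm_len - 3, spec.cterm_n_cys).astype(int)
        for i in cys_at:
            cbody[i] = "C"
    cterm = "".join(cbody)

    protein = signal + nbody + spec.linker + core + cterm

    spans: list[MotifSpan] = []
    pos = 1

    def plant(cls: str, seq: str) -> None:
        nonlocal pos
        if seq:
            spans.append(MotifSpan(cls, pos, pos + len(seq) - 1, seq))
            pos += len(seq)

    plant("SIGNAL", signal)
    plant("N_AMORPH", nbody)
    plant("LINKER", spec.linker)
    for cls, seq in core_parts:
        plant(cls, seq)
    plant("C_AMORPH", cterm)

    # --- CDS and gene -----------------------------------------------------
    cds, codon_draws = reverse_translate(protein, spec.isocodon_freqs, rng)

    utr5 = _random_dna(rng, spec.utr5_len, gc=0.35)
    intron = _make_intron(rng, spec.intron_len, spec.intron_gc)
    tail_len = spec.utr3_len - 3
    while True:
        before = _random_dna(rng, spec.polya_offset, gc=0.35)
        # the planted signal must be the first AATAAA downstream of the stop
        if (before + "AATAAA").find("AATAAA") == len(before):
            break
    after = _random_dna(rng, tail_len - spec.polya_offset - 6, gc=0.35)
    utr3 = "TAA" + before + "AATAAA" + after

    upstream = list(_random_dna(rng, spec.upstream_len, gc=0.35))

    def plant_element(offset: int, motif: str) -> int:
        start0 = spec.upstream_len + offset  # offset is negative
        upstream[start0 : start0 + len(motif)] = motif
        return start0 + 1  # 1-based on the gene (upstream starts the gene)

    caat_pos = plant_element(spec.caat_offset, "CCAAT")
    sgf_pos = plant_element(spec.sgf_offset, "TGTTT")
    tata_pos = plant_element(spec.tata_offset, "TATAAA")
    upstream = "".join(upstream)

    exon1 = utr5 + cds[: spec.exon1_coding_len]
    exon2 = cds[spec.exon1_coding_len :] + utr3
    gene_seq = upstream + exon1 + intron + exon2
    gene = NucSeq(id="synthetic_fibroin", residues=gene_seq, description="synthetic fibroin-like gene")

    u = spec.upstream_len
    e1_start, e1_end = u + 1, u + len(exon1)
    i_start, i_end = e1_end + 1, e1_end + spec.intron_len
    e2_start, e2_end = i_end + 1, i_end + len(exon2)
    stop_start = e2_end - spec.utr3_len + 1
    features = [
        SeqFeature("promoter_element", caat_pos, caat_pos + 4, "+", "CAAT"),
        SeqFeature("promoter_element", sgf_pos, sgf_pos + 4, "+", "SGF"),
        SeqFeature("promoter_element", tata_pos, tata_pos + 5, "+", "TATA"),
        SeqFeature("exon", e1_start, e1_end, "+", "exon1"),
        SeqFeature("utr5", e1_start, e1_start + spec.utr5_len - 1, "+", "utr5"),
        SeqFeature("cds", e1_start + spec.utr5_len, e1_end, "+", "cds_exon1"),
        SeqFeature("intron", i_start, i_end, "+", "intron"),
        SeqFeature("exon", e2_start, e2_end, "+", "exon2"),
        SeqFeature("cds", e2_start, stop_start - 1, "+", "cds_exon2"),
        SeqFeature("utr3", stop_start, e2_end, "+", "utr3"),
        SeqFeature(
            "polyA_signal",
            stop_start + 3 + spec.polya_offset,
            stop_start + 3 + spec.polya_offset + 5,
            "+",
            "AATAAA",
        ),
    ]

    return GroundTruth(
        protein=protein,
        spans=spans,
        gene=gene,
        features=features,
        codon_draws=codon_draws,
        spec=spec,
    )
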