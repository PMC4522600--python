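"""Repeat-motif grammar of the H-fibroin crystalline core.

The mature protein is modelled as

    [signal][N-amorphous][Ser linker][alternating A / non-A motif core][C-amorphous]

where A-motifs are maximal polyalanine runs (5-15 residues in this fibroin)
and the intervening non-polyalanine motifs are Arg-rich R-motifs or Gly-rich
G-motifs. G-motifs share a proximal GSGAGG-like anchor and fall into three
length classes (Ga ~18, Gb ~19-21, Gc >=22 residues). Segmentation tiles the
protein: concatenating the spans reconstructs it exactly.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .gene_model import iupac_regex
from .io_formats import FibroinError, NucSeq

MOTIF_CLASSES = ("SIGNAL", "N_AMORPH", "LINKER", "A", "R", "Ga", "Gb", "Gc", "G_OTHER", "C_AMORPH")
G_CLASSES = ("Ga", "Gb", "Gc", "G_OTHER")

#: Default Chi-like recombination motif; never spelled out for this gene, so
#: it is a user-overridable assumption.
DEFAULT_CHI_LIKE = "GCTGGTGG"


@dataclass
class SegmentationParams:
    """Tunable thresholds of the motif grammar (defaults calibrated for AaFhc)."""

    signal_len: int = 18
    n_amorphous_len: int = 127  # includes the signal peptide
    c_amorphous_len: int = 34
    a_min_run: int = 5
    r_arg_min_frac: float = 0.15
    g_gly_min_frac: float = 0.30
    g_anchor: str = "GSGAGG"
    g_anchor_max_mismatch: int = 2
    ga_len: int = 18
    gc_min_len: int = 22
    linker_min_ser_run: int = 6
    min_inter_motif_len: int = 3  # shorter inter-A intervals merge into the preceding span

    def __post_init__(self) -> None:
        if self.a_min_run <= 0:
            raise FibroinError("a_min_run must be positive")
        for name in ("r_arg_min_frac", "g_gly_min_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FibroinError(f"{name} must lie in [0, 1]")
        if self.ga_len >= self.gc_min_len:
            raise FibroinError("ga_len must be smaller than gc_min_len")


@dataclass
class MotifSpan:
    """A classified span over the protein, 1-based inclusive residue coordinates."""

    cls: str
    start: int
    end: int
    seq: str

    def __post_init__(self) -> None:
        if self.cls not in MOTIF_CLASSES:
            raise FibroinError(f"unknown motif class {self.cls!r}")
        if not (1 <= self.start <= self.end):
            raise FibroinError(f"bad span {self.start}..{self.end}")
        if len(self.seq) != self.end - self.start + 1:
            raise FibroinError("span sequence length disagrees with coordinates")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinArchitecture:
    """Ordered tiling of a protein into classified motif spans."""

    protein: str
    spans: list[MotifSpan]
    params: SegmentationParams

    def __post_init__(self) -> None:
        if "".join(s.seq for s in self.spans) != self.protein:
            raise FibroinError("spans do not tile the protein")
        pos = 1
        for s in self.spans:
            if s.start != pos:
                raise FibroinError(f"gap/overlap before span at {s.start} (expected {pos})")
            pos = s.end + 1

    def of_class(self, *classes: str) -> list[MotifSpan]:
        return [s for s in self.spans if s.cls in classes]

    @property
    def core_spans(self) -> list[MotifSpan]:
        return self.of_class("A", "R", "Ga", "Gb", "Gc", "G_OTHER")


# ---------------------------------------------------------------------------
# Segmentation


def segment_termini(
    protein: str, params: SegmentationParams | None = None
) -> tuple[str, str, str, str, str]:
    """Split the protein into (signal, n_amorph, linker, core, c_amorph).

    The signal peptide and N-amorphous block are fixed-length prefixes (the
    N-amorphous length includes the signal); the C-amorphous block is a
    fixed-length suffix. The linker is the maximal run of serines immediately
    after the N-amorphous block, kept only when it reaches
    ``linker_min_ser_run``.
    """
    p = params or SegmentationParams()
    if len(protein) <= p.n_amorphous_len + p.c_amorphous_len:
        raise FibroinError(
            f"protein of {len(protein)} aa too short for termini of "
            f"{p.n_amorphous_len}+{p.c_amorphous_len} aa"
        )
    signal = protein[: p.signal_len]
    n_amorph = protein[p.signal_len : p.n_amorphous_len]
    rest = protein[p.n_amorphous_len : len(protein) - p.c_amorphous_len]
    c_amorph = protein[len(protein) - p.c_amorphous_len :]
    run = 0
    while run < len(rest) and rest[run] == "S":
        run += 1
    if run >= p.linker_min_ser_run:
        linker, core = rest[:run], rest[run:]
    else:
        linker, core = "", rest
    return signal, n_amorph, linker, core, c_amorph


def detect_a_motifs(core: str, a_min_run: int = 5) -> list[tuple[int, int]]:
    """Maximal polyalanine runs of length >= ``a_min_run`` (1-based spans on core)."""
    if not core:
        raise FibroinError("empty core")
    spans = []
    i = 0
    n = len(core)
    while i < n:
        if core[i] == "A":
            j = i
            while j < n and core[j] == "A":
                j += 1
            if j - i >= a_min_run:
                spans.append((i + 1, j))
            i = j
        else:
            i += 1
    return spans


def subtype_g(seq: str, params: SegmentationParams | None = None) -> str:
    """Assign a Gly-rich span to Ga/Gb/Gc by its proximal anchor and length.

    Spans without the GSGAGG-like anchor (within the mismatch budget) at the
    proximal end are G_OTHER; anchored spans are binned by length.
    """
    p = params or SegmentationParams()
    anchor = p.g_anchor
    head = seq[: len(anchor)]
    if len(head) < len(anchor):
        return "G_OTHER"
    mismatches = sum(a != b for a, b in zip(head, anchor))
    if mismatches > p.g_anchor_max_mismatch:
        return "G_OTHER"
    if len(seq) <= p.ga_len:
        return "Ga"
    if len(seq) >= p.gc_min_len:
        return "Gc"
    return "Gb"


def _classify_interval(seq: str, params: SegmentationParams) -> str:
    counts = Counter(seq)
    if counts.get("R", 0) / len(seq) >= params.r_arg_min_frac:
        return "R"
    if counts.get("G", 0) / len(seq) >= params.g_gly_min_frac:
        return subtype_g(seq, params)
    return "G_OTHER"


def classify_inter_motifs(
    core: str,
    a_spans: list[tuple[int, int]],
    params: SegmentationParams | None = None,
) -> list[MotifSpan]:
    """Tile the core into A spans and classified inter-A motif spans.

    Inter-A intervals shorter than ``min_inter_motif_len`` are merged into the
    preceding span (into the following one at the very start of the core), so
    noisy input cannot create degenerate one-residue motifs.
    """
    p = params or SegmentationParams()
    spans: list[MotifSpan] = []
    pos = 1

    def emit(start: int, end: int, cls: str | None) -> None:
        seq = core[start - 1 : end]
        if cls != "A" and len(seq) < p.min_inter_motif_len:
            if spans:  # fold the short fragment into the preceding span
                prev = spans[-1]
                spans[-1] = MotifSpan(prev.cls, prev.start, end, prev.seq + seq)
            else:  # nothing precedes it: defer, fold into the next span
                spans.append(MotifSpan("G_OTHER", start, end, seq))
                pending.append(len(spans) - 1)
            return
        if cls is None:
            cls = _classify_interval(seq, p)
        spans.append(MotifSpan(cls, start, end, seq))

    pending: list[int] = []
    for a_start, a_end in a_spans:
        if a_start > pos:
            emit(pos, a_start - 1, None)
        emit(a_start, a_end, "A")
        pos = a_end + 1
    if pos <= len(core):
        emit(pos, len(core), None)

    if pending and len(spans) > 1:
        head, nxt = spans[0], spans[1]
        spans[1] = MotifSpan(nxt.cls, head.start, nxt.end, head.seq + nxt.seq)
        spans = spans[1:]
    return spans


def segment(protein: str, params: SegmentationParams | None = None) -> ProteinArchitecture:
    """Full segmentation of a mature H-fibroin-like protein into motif spans."""
    p = params or SegmentationParams()
    signal, n_amorph, linker, core, c_amorph = segment_termini(protein, p)
    spans: list[MotifSpan] = []
    pos = 1

    def push(cls: str, seq: str) -> None:
        nonlocal pos
        if seq:
            spans.append(MotifSpan(cls, pos, pos + len(seq) - 1, seq))
            pos += len(seq)

    push("SIGNAL", signal)
    push("N_AMORPH", n_amorph)
    push("LINKER", linker)
    core_offset = pos - 1
    a_spans = detect_a_motifs(core, p.a_min_run)
    for s in classify_inter_motifs(core, a_spans, p):
        spans.append(MotifSpan(s.cls, s.start + core_offset, s.end + core_offset, s.seq))
    pos = spans[-1].end + 1
    push("C_AMORPH", c_amorph)
    return ProteinArchitecture(protein=protein, spans=spans, params=p)


# ---------------------------------------------------------------------------
# Censuses and profiles


def count_tripeptide(region: str, tri: str, overlapping: bool = True) -> int:
    """Occurrences of a tripeptide in a region (overlapping by default)."""
    if len(tri) != 3:
        raise FibroinError("tripeptide must have length 3")
    if not region:
        return 0
    count = 0
    step = 1 if overlapping else 3
    i = region.find(tri)
    if overlapping:
        while i >= 0:
            count += 1
            i = region.find(tri, i + 1)
    else:
        while i >= 0:
            count += 1
            i = region.find(tri, i + 3)
    return count


def motif_inventory(arch: ProteinArchitecture) -> dict:
    """Per-class counts, length stats and residue fractions of an architecture."""
    core = arch.core_spans
    core_len = sum(len(s) for s in core)
    total_ala = arch.protein.count("A")
    ala_in_a = sum(s.seq.count("A") for s in arch.of_class("A"))
    by_class: dict[str, dict] = {}
    for cls in ("A", "R", "Ga", "Gb", "Gc", "G_OTHER"):
        members = arch.of_class(cls)
        lengths = [len(s) for s in members]
        by_class[cls] = {
            "count": len(members),
            "min_len": min(lengths) if lengths else 0,
            "max_len": max(lengths) if lengths else 0,
            "mean_len": float(np.mean(lengths)) if lengths else 0.0,
            "residues": sum(lengths),
            "pct_of_core": 100.0 * sum(lengths) / core_len if core_len else 0.0,
        }
    g_strict = sum(by_class[c]["count"] for c in ("Ga", "Gb", "Gc"))
    g_total = g_strict + by_class["G_OTHER"]["count"]
    return {
        "classes": by_class,
        "core_residues": core_len,
        "n_motifs": len(core),
        "g_motifs_strict": g_strict,
        "g_motifs_total": g_total,
        "pct_total_ala_in_a_motifs": 100.0 * ala_in_a / total_ala if total_ala else 0.0,
        "pct_protein_ala_in_a_motifs": 100.0 * ala_in_a / len(arch.protein),
    }


GAP = "-"


def conservation_profile(motifs: list[str]) -> tuple[list[dict[str, float]], str]:
    """Position-frequency matrix over same-class motifs (no alignment performed).

    Ragged motifs are right-padded with a gap symbol; per-column frequencies
    are over non-gap residues and sum to 1. Returns (columns, consensus);
    consensus ties break lexicographically.
    """
    if not motifs:
        raise FibroinError("need at least one motif")
    width = max(len(m) for m in motifs)
    padded = [m.ljust(width, GAP) for m in motifs]
    columns: list[dict[str, float]] = []
    consensus = []
    for j in range(width):
        col = [m[j] for m in padded if m[j] != GAP]
        counts = Counter(col)
        total = sum(counts.values())
        freqs = {aa: counts[aa] / total for aa in sorted(counts)}
        columns.append(freqs)
        consensus.append(max(sorted(freqs), key=lambda aa: freqs[aa]))
    return columns, "".join(consensus)


def find_dna_motif(seq: NucSeq | str, motif: str = DEFAULT_CHI_LIKE) -> list[int]:
    """All 1-based coding-strand match positions of an IUPAC DNA motif."""
    s = seq.residues if isinstance(seq, NucSeq) else seq.upper()
    rx = iupac_regex(motif)
    out = []
    i = 0
    while True:
        m = rx.search(s, i)
        if m is None:
            return out
        out.append(m.start() + 1)
        i = m.start() + 1


def find_rgd(protein: str) -> list[int]:
    """1-based positions of the integrin-binding RGD tripeptide."""
    out = []
    i = protein.find("RGD")
    while i >= 0:
        out.append(i + 1)
        i = protein.find("RGD", i + 1)
    return out
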