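"""In-silico restriction digestion: site finding, complete/partial digests,
co-migrant fragment banding and text restriction maps.

Cut positions are single top-strand coordinates (the base *after* which the
top strand is cut); overhang chemistry is not modelled because fragment
lengths, the only quantity downstream analyses use, do not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

from .gene_model import iupac_regex, revcomp
from .io_formats import FibroinError, NucSeq


@dataclass(frozen=True)
class Enzyme:
    """A restriction endonuclease: IUPAC recognition site and top-strand cut offset."""

    name: str
    site: str
    cut_offset: int  # bases from site start; cut falls after this many bases

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise FibroinError(f"{self.name}: recognition site must be >= 4 nt")
        if not 0 <= self.cut_offset <= len(self.site):
            raise FibroinError(f"{self.name}: cut offset outside the site")

    @property
    def is_palindromic(self) -> bool:
        return revcomp(self.site) == self.site.upper()


#: The enzymes used to subclone this fibroin gene (caret = cut position).
BUILTIN_ENZYMES: dict[str, Enzyme] = {
    e.name: e
    for e in (
        Enzyme("HhaI", "GCGC", 3),
        Enzyme("HaeIII", "GGCC", 2),
        Enzyme("NotI", "GCGGCCGC", 2),
        Enzyme("BamHI", "GGATCC", 1),
        Enzyme("EcoRV", "GATATC", 3),
        Enzyme("Bsu36I", "CCTNAGG", 2),
    )
}


def get_enzyme(name: str) -> Enzyme:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise FibroinError(
            f"unknown enzyme {name!r}; built-ins: {', '.join(sorted(BUILTIN_ENZYMES))}"
        ) from None


def read_enzyme_table(path) -> list[Enzyme]:
    """Read a user enzyme config (TSV: name, site, cut_offset)."""
    enzymes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FibroinError(f"{path}:{lineno}: expected name/site/cut_offset")
            enzymes.append(Enzyme(parts[0], parts[1].upper(), int(parts[2])))
    return enzymes


def find_sites(seq: NucSeq | str, enzyme: Enzyme, topology: str = "linear") -> list[int]:
    """1-based top-strand start positions of all recognition sites, both strands.

    Bottom-strand matches are reported by the top-strand coordinates of their
    footprint; palindromic duplicates are removed. On circular molecules the
    doubled sequence is scanned so origin-spanning sites are found.
    """
    s = seq.residues if isinstance(seq, NucSeq) else seq.upper()
    n = len(s)
    scan = s + s[: len(enzyme.site) - 1] if topology == "circular" else s
    rx = iupac_regex(enzyme.site)
    positions = set()
    for rx_strand, pattern in ((rx, enzyme.site), (iupac_regex(revcomp(enzyme.site)), None)):
        if pattern is None and enzyme.is_palindromic:
            continue  # bottom strand footprint identical for palindromic sites
        i = 0
        while True:
            m = rx_strand.search(scan, i)
            if m is None or m.start() >= n:
                break
            positions.add(m.start() + 1)
            i = m.start() + 1
    return sorted(positions)


def _cut_positions(seq: NucSeq | str, enzymes: list[Enzyme], topology: str) -> list[int]:
    s = seq.residues if isinstance(seq, NucSeq) else seq.upper()
    n = len(s)
    cuts = set()
    for enz in enzymes:
        for site_start in find_sites(s, enz, topology):
            cut = site_start + enz.cut_offset - 1  # base after which the strand parts
            if topology == "circular":
                cut = ((cut - 1) % n) + 1
                cuts.add(cut)
            elif 1 <= cut < n:  # cuts at the very ends release nothing
                cuts.add(cut)
    return sorted(cuts)


@dataclass
class Fragment:
    start: int
    end: int  # 1-based inclusive; end < start never occurs on linear molecules

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class DigestResult:
    """Cut positions and resulting fragment intervals of one digestion."""

    seq_id: str
    seq_length: int
    enzymes: list[str]
    topology: str
    cut_positions: list[int]
    fragments: list[Fragment]

    def __post_init__(self) -> None:
        total = sum(f.length for f in self.fragments)
        if self.topology == "linear":
            assert total == self.seq_length, "fragment lengths must sum to input length"
            assert len(self.fragments) == len(self.cut_positions) + 1
        elif self.cut_positions:
            assert total == self.seq_length
            assert len(self.fragments) == len(self.cut_positions)

    @property
    def fragment_lengths(self) -> list[int]:
        return sorted((f.length for f in self.fragments), reverse=True)


def digest_complete(
    seq: NucSeq | str,
    enzymes: list[Enzyme] | list[str],
    topology: str | None = None,
) -> DigestResult:
    """Complete digestion with one or more enzymes (cut sets are merged)."""
    if not enzymes:
        raise FibroinError("need at least one enzyme")
    enzymes = [get_enzyme(e) if isinstance(e, str) else e for e in enzymes]
    if isinstance(seq, str):
        seq = NucSeq(id="seq", residues=seq)
    topology = topology or seq.topology
    n = len(seq)
    cuts = _cut_positions(seq, enzymes, topology)
    fragments: list[Fragment] = []
    if topology == "linear":
        bounds = [0] + cuts + [n]
        fragments = [Fragment(a + 1, b) for a, b in zip(bounds, bounds[1:])]
    else:
        if not cuts:
            fragments = [Fragment(1, n)]  # intact circle
        else:
            for a, b in zip(cuts, cuts[1:]):
                fragments.append(Fragment(a + 1, b))
            fragments.append(Fragment(cuts[-1] + 1, n + cuts[0]))  # wraps the origin
    return DigestResult(
        seq_id=seq.id,
        seq_length=n,
        enzymes=[e.name for e in enzymes],
        topology=topology,
        cut_positions=cuts,
        fragments=fragments,
    )


def digest_partial(
    seq: NucSeq | str,
    enzyme: Enzyme | str,
    max_products: int = 10_000,
) -> list[Fragment]:
    """Every partial-digest product of a linear molecule.

    Each product is delimited by any pair of boundaries drawn from
    {start, internal cuts..., end}: C(k+2, 2) products for k internal cuts.
    """
    if isinstance(seq, str):
        seq = NucSeq(id="seq", residues=seq)
    if seq.topology != "linear":
        raise FibroinError("partial digestion is defined for linear molecules")
    enzyme = get_enzyme(enzyme) if isinstance(enzyme, str) else enzyme
    cuts = _cut_positions(seq, [enzyme], "linear")
    n_products = comb(len(cuts) + 2, 2)
    if n_products > max_products:
        raise FibroinError(
            f"{n_products} partial products exceed the cap of {max_products}; "
            "use an enzyme with fewer sites or raise max_products"
        )
    bounds = [0] + cuts + [len(seq)]
    return [Fragment(a + 1, b) for a, b in combinations(bounds, 2)]


@dataclass
class Band:
    """A gel band: fragments too close in size to resolve run as co-migrants."""

    label: int
    fragments: list[Fragment]

    @property
    def sizes(self) -> list[int]:
        return [f.length for f in self.fragments]

    def co_migrant_labels(self) -> list[str]:
        if len(self.fragments) == 1:
            return [str(self.label)]
        return [f"{self.label}{chr(ord('a') + i)}" for i in range(len(self.fragments))]


def fragment_size_table(
    fragments: list[Fragment] | DigestResult,
    resolution_bp: int = 10,
    seq_length: int | None = None,
) -> list[Band]:
    """Group fragments into bands by single-linkage at the gel resolution.

    Fragments are sorted descending; a fragment joins the current band when it
    lies within ``resolution_bp`` of the band's nearest (smallest) member,
    mirroring how near-equal fragments co-migrate on a gel.
    """
    if isinstance(fragments, DigestResult):
        seq_length = fragments.seq_length
        fragments = fragments.fragments
    ordered = sorted(fragments, key=lambda f: (-f.length, f.start))
    bands: list[Band] = []
    for frag in ordered:
        if bands and bands[-1].fragments[-1].length - frag.length <= resolution_bp:
            bands[-1].fragments.append(frag)
        else:
            bands.append(Band(label=len(bands) + 1, fragments=[frag]))
    return bands


def band_table_frame(bands: list[Band], seq_length: int | None = None):
    """Banded fragment table as a DataFrame (terminal fragments flagged)."""
    import pandas as pd

    rows = []
    for band in bands:
        for lab, frag in zip(band.co_migrant_labels(), band.fragments):
            terminal = frag.start == 1 or (seq_length is not None and frag.end == seq_length)
            rows.append(
                {
                    "band": band.label,
                    "fragment": lab,
                    "start": frag.start,
                    "end": frag.end,
                    "length_bp": frag.length,
                    "terminal": bool(terminal),
                }
            )
    return pd.DataFrame(rows, columns=["band", "fragment", "start", "end", "length_bp", "terminal"])


def render_map(result: DigestResult) -> str:
    """Deterministic text restriction map: sites and inter-site distances."""
    lines = [
        f"# restriction map of {result.seq_id} ({result.seq_length} bp, {result.topology})",
        f"# enzymes: {', '.join(result.enzymes)}",
    ]
    prev = 0
    for cut in result.cut_positions:
        lines.append(f"cut after {cut}\t(segment of {cut - prev} bp)")
        prev = cut
    lines.append(f"end {result.seq_length}\t(segment of {result.seq_length - prev} bp)")
    segments = [f.length for f in result.fragments]
    lines.append(f"# fragments: {' '.join(str(s) for s in sorted(segments, reverse=True))}")
    return "\n".join(lines) + "\n"
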