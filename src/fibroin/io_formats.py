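"""Core sequence/feature types and readers/writers for the formats the pipeline touches.

Coordinates are 1-based inclusive everywhere at the interface (GenBank
convention); any half-open arithmetic is internal and invisible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide one-letter codes (DNA + RNA U), stored uppercase.
IUPAC_NUCLEOTIDES = frozenset("ACGTURYSWKMBDHVN")

FEATURE_KINDS = frozenset(
    {
        "exon",
        "intron",
        "utr5",
        "utr3",
        "cds",
        "promoter_element",
        "polyA_signal",
        "motif",
        "enzyme_site",
    }
)


class FibroinError(ValueError):
    """Base error for malformed inputs."""


@dataclass
class NucSeq:
    """A named nucleotide sequence.

    Residues are validated against the IUPAC nucleotide alphabet and stored
    uppercase; lowercase input (e.g. GenBank ORIGIN blocks) is accepted.
    """

    id: str
    residues: str
    description: str = ""
    topology: str = "linear"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if len(self.residues) == 0:
            raise FibroinError(f"sequence {self.id!r} is empty")
        if self.topology not in ("linear", "circular"):
            raise FibroinError(f"topology must be linear or circular, got {self.topology!r}")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in IUPAC_NUCLEOTIDES:
                raise FibroinError(
                    f"sequence {self.id!r}: non-IUPAC nucleotide {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        """Residues from ``start`` to ``end``, 1-based inclusive."""
        if not (1 <= start <= end <= len(self.residues)):
            raise FibroinError(f"slice {start}..{end} out of range for length {len(self)}")
        return self.residues[start - 1 : end]


@dataclass
class SeqFeature:
    """A located annotation on a parent sequence (1-based inclusive)."""

    kind: str
    start: int
    end: int
    strand: str = "+"
    label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise FibroinError(f"unknown feature kind {self.kind!r}")
        if self.start < 1:
            raise FibroinError(f"feature {self.label!r}: start {self.start} < 1 (1-based)")
        if self.start > self.end:
            raise FibroinError(f"feature {self.label!r}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise FibroinError(f"feature {self.label!r}: strand must be + or -")

    def __len__(self) -> int:
        return self.end - self.start + 1


def validate_features(features: Iterable[SeqFeature], parent_length: int) -> None:
    """Check coordinates against the parent and exon/intron disjointness."""
    structural = []
    for f in features:
        if f.end > parent_length:
            raise FibroinError(
                f"feature {f.label!r} ends at {f.end}, beyond parent length {parent_length}"
            )
        if f.kind in ("exon", "intron"):
            structural.append(f)
    structural.sort(key=lambda f: f.start)
    for a, b in zip(structural, structural[1:]):
        if b.start <= a.end:
            raise FibroinError(
                f"features {a.label!r} and {b.label!r} overlap ({a.start}..{a.end} vs {b.start}..{b.end})"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> list[NucSeq]:
    """Read a (multi-)FASTA file into validated :class:`NucSeq` records."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FibroinError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        out.append(NucSeq(id=rec.id, residues=str(rec.seq), description=desc))
    return out


def write_fasta(seqs: Iterable[NucSeq], path: str | Path, width: int = 70) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.description) for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def read_protein_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read protein FASTA as (id, uppercase sequence) pairs (no NucSeq validation)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FibroinError(f"{path}: no FASTA records found")
    return [(rec.id, str(rec.seq).upper()) for rec in records]


# ---------------------------------------------------------------------------
# Feature tables (TSV: kind, start, end, strand, label)

_TSV_COLUMNS = ("kind", "start", "end", "strand", "label")


def read_feature_table(path: str | Path) -> list[SeqFeature]:
    """Read a tab-separated feature table, returning features sorted by start.

    A header row equal to the canonical column names is tolerated.
    """
    feats: list[SeqFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0] == "kind":
                continue
            if len(parts) < 4:
                raise FibroinError(f"{path}:{lineno}: expected >=4 tab-separated fields")
            kind, start, end = parts[0], parts[1], parts[2]
            strand = parts[3] if len(parts) > 3 and parts[3] else "+"
            label = parts[4] if len(parts) > 4 else ""
            try:
                feats.append(
                    SeqFeature(kind=kind, start=int(start), end=int(end), strand=strand, label=label)
                )
            except FibroinError as e:
                raise FibroinError(f"{path}:{lineno}: {e}") from e
    feats.sort(key=lambda f: (f.start, f.end))
    return feats


def write_feature_table(features: Iterable[SeqFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for f in features:
            fh.write(f"{f.kind}\t{f.start}\t{f.end}\t{f.strand}\t{f.label}\n")


# ---------------------------------------------------------------------------
# Minimal GenBank ingestion (convenience; full compliance is a non-goal)

_GENBANK_KIND_MAP = {
    "exon": "exon",
    "intron": "intron",
    "CDS": "cds",
    "5'UTR": "utr5",
    "3'UTR": "utr3",
}


def read_genbank(path: str | Path) -> tuple[NucSeq, list[SeqFeature]]:
    """Read one GenBank record, keeping exon/intron/CDS/UTR features only."""
    rec = SeqIO.read(str(path), "genbank")
    seq = NucSeq(id=rec.id, residues=str(rec.seq), description=rec.description)
    feats = []
    for f in rec.features:
        kind = _GENBANK_KIND_MAP.get(f.type)
        if kind is None:
            continue
        for part in f.location.parts:
            feats.append(
                SeqFeature(
                    kind=kind,
                    start=int(part.start) + 1,  # Biopython is 0-based half-open
                    end=int(part.end),
                    strand="+" if (part.strand or 1) >= 0 else "-",
                    label=str(f.qualifiers.get("gene", [f.type])[0]),
                )
            )
    feats.sort(key=lambda f: (f.start, f.end))
    return seq, feats


# ---------------------------------------------------------------------------
# Reports


def _round_reals(obj):
    if isinstance(obj, float):
        return round(obj, 4)
    if isinstance(obj, Mapping):
        return {k: _round_reals(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_reals(v) for v in obj]
    return obj


def _flatten(obj, prefix="") -> list[tuple[str, object]]:
    rows: list[tuple[str, object]] = []
    if isinstance(obj, Mapping):
        for k, v in obj.items():
            rows.extend(_flatten(v, f"{prefix}{k}." if prefix or True else k))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            rows.extend(_flatten(v, f"{prefix}{i}."))
    else:
        rows.append((prefix.rstrip("."), obj))
    return rows


def write_report(results: Mapping, path: str | Path, format: str = "json") -> None:
    """Write an analysis report deterministically.

    Integers round-trip bit-exactly; reals are written to 4 decimals. Field
    order follows the mapping's insertion order in both formats.
    """
    results = _round_reals(results)
    path = Path(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(results, fh, indent=2)
            fh.write("\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write("key\tvalue\n")
            for key, val in _flatten(results):
                fh.write(f"{key}\t{val}\n")
    else:
        raise FibroinError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        return json.load(fh)
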