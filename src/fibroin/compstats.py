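"""Regional amino-acid composition, hydropathy, mass and isoelectric point.

Hydropathy uses the Kyte-Doolittle scale; masses are average (not
monoisotopic) residue masses, matching gel-scale estimates; the isoelectric
point uses the Bjellqvist pKa set and bisection on the net-charge function.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.SeqUtils import molecular_weight as _bio_mw
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

from .io_formats import FibroinError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Residue grouping used throughout the composition tables. Polar = Ser, Thr,
#: Tyr, Cys, Asn, Gln plus all charged residues; acidic = Asp, Glu; basic =
#: Lys, Arg, His; nonpolar = the remainder.
ACIDIC = frozenset("DE")
BASIC = frozenset("KRH")
POLAR = frozenset("STYCNQ") | ACIDIC | BASIC
NONPOLAR = frozenset(AMINO_ACIDS) - POLAR

#: Bjellqvist pKa values: side chains and termini.
BJELLQVIST_PKA = {
    "D": 4.05,
    "E": 4.45,
    "H": 5.98,
    "C": 9.0,
    "Y": 10.0,
    "K": 10.0,
    "R": 12.0,
    "Nterm": 7.5,
    "Cterm": 3.55,
}
_NEGATIVE = ("D", "E", "C", "Y", "Cterm")
_POSITIVE = ("H", "K", "R", "Nterm")


def _check_peptide(region: str) -> str:
    if not region:
        raise FibroinError("empty peptide")
    region = region.upper()
    for i, aa in enumerate(region, start=1):
        if aa not in AMINO_ACIDS:
            raise FibroinError(f"non-amino-acid character {aa!r} at position {i}")
    return region


@dataclass
class CompositionTable:
    """Exact per-residue counts and derived group fractions for one region."""

    region: str
    counts: dict[str, int]
    percentages: dict[str, float]
    polar_frac: float
    nonpolar_frac: float
    acidic_count: int
    basic_count: int
    acidic_basic_ratio: float | None

    @property
    def length(self) -> int:
        return sum(self.counts.values())


def composition(region: str, label: str = "region") -> CompositionTable:
    """Amino-acid composition of a peptide with polar/nonpolar/charge groupings."""
    region = _check_peptide(region)
    counts = Counter(region)
    n = len(region)
    full = {aa: counts.get(aa, 0) for aa in AMINO_ACIDS}
    acidic = sum(full[aa] for aa in ACIDIC)
    basic = sum(full[aa] for aa in BASIC)
    return CompositionTable(
        region=label,
        counts=full,
        percentages={aa: 100.0 * full[aa] / n for aa in AMINO_ACIDS},
        polar_frac=sum(full[aa] for aa in POLAR) / n,
        nonpolar_frac=sum(full[aa] for aa in NONPOLAR) / n,
        acidic_count=acidic,
        basic_count=basic,
        acidic_basic_ratio=(acidic / basic) if basic else None,
    )


def gravy(region: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value over the peptide."""
    region = _check_peptide(region)
    return float(np.mean([KYTE_DOOLITTLE[aa] for aa in region]))


@dataclass
class HydropathyProfile:
    window: int
    scores: np.ndarray
    scale: str = "Kyte-Doolittle"

    @property
    def sign_changes(self) -> int:
        """Hydrophobic/hydrophilic alternations along the profile."""
        signs = np.sign(self.scores)
        signs = signs[signs != 0]
        return int(np.sum(signs[1:] != signs[:-1]))


def hydropathy_profile(region: str, window: int = 9) -> HydropathyProfile:
    """Sliding-window mean hydropathy (one score per valid window position)."""
    region = _check_peptide(region)
    if window < 1 or window > len(region):
        raise FibroinError(f"window {window} invalid for peptide of {len(region)} aa")
    values = np.array([KYTE_DOOLITTLE[aa] for aa in region], dtype=float)
    kernel = np.ones(window) / window
    scores = np.convolve(values, kernel, mode="valid")
    return HydropathyProfile(window=window, scores=scores)


WATER_MASS = 18.0153


def molecular_weight(region: str) -> float:
    """Average molecular mass of the peptide in daltons (residues + one water)."""
    region = _check_peptide(region)
    return float(_bio_mw(region, seq_type="protein", monoisotopic=False))


def net_charge(region: str, pH: float, pka: dict[str, float] | None = None) -> float:
    """Henderson-Hasselbalch net charge of the peptide at a given pH.

    Charged groups: free termini plus D/E/H/C/Y/K/R side chains.
    """
    region = _check_peptide(region)
    pka = pka or BJELLQVIST_PKA
    counts = Counter(region)
    counts["Nterm"] = counts["Cterm"] = 1
    charge = 0.0
    for grp in _POSITIVE:
        charge += counts.get(grp, 0) / (1.0 + 10.0 ** (pH - pka[grp]))
    for grp in _NEGATIVE:
        charge -= counts.get(grp, 0) / (1.0 + 10.0 ** (pka[grp] - pH))
    return charge


def isoelectric_point(
    region: str,
    pka: dict[str, float] | None = None,
    charge_tol: float = 1e-4,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so the root is unique;
    the bracket is asserted at every iteration.
    """
    lo, hi = 0.0, 14.0
    c_lo, c_hi = net_charge(region, lo, pka), net_charge(region, hi, pka)
    if c_lo <= 0:
        return lo
    if c_hi >= 0:
        return hi
    for _ in range(200):
        assert c_lo > 0 > c_hi, "bisection bracket lost"
        mid = 0.5 * (lo + hi)
        c_mid = net_charge(region, mid, pka)
        if abs(c_mid) < charge_tol:
            return mid
        if c_mid > 0:
            lo, c_lo = mid, c_mid
        else:
            hi, c_hi = mid, c_mid
    return 0.5 * (lo + hi)
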