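# Methods

## The gene model and its arithmetic

A saturniid H-fibroin gene is modelled as a two-exon structure (the code
accepts any exon count) with short UTRs and a short AT-rich intron near the
5′ end. One bookkeeping convention drives all length arithmetic: **the stop
codon is the first codon of the 3′ UTR**, so the CDS excludes it. Under this
convention, for the *A. assama* gene plan,

- transcript = Σ exon lengths = 27 (5′ UTR) + 8427 (CDS) + 78 (3′ UTR) = 8532 nt,
- CDS = 42 (exon-1 coding) + 8385 (exon-2 coding) = 8427 nt = 2809 codons,
- genomic ATG–TAA span = 42 + 131 (intron) + 8385 + 3 (stop) = 8561 bp.

`GeneStructure` asserts this identity on construction and
`gene_check_report` emits it as a consistency report. Non-canonical intron
boundaries (not GT…AG) raise a warning, not an error, so synthetic test
introns are tolerated. Offsets upstream of the transcription start are
signed with no position 0: −1 is the base immediately 5′ of +1, and a
promoter hit is reported at the offset of its 5′-most base. Default element
patterns (IUPAC, all configurable): TATA `TATAWA`, CAAT `CCAAT`,
silk-gland factor `TGTTT`.

Palindrome search returns maximal substrings equal to their own reverse
complement (necessarily even length), by symmetric expansion around each
inter-base center; no secondary-structure folding is attempted.

## The motif grammar

The mature protein is segmented as

```
[signal 18][N-amorphous to 127][Ser linker >= 6][core][C-amorphous 34]
```

The terminal lengths are fixed-length parameters (`SegmentationParams`),
with the N-amorphous length counted **including** the signal peptide. The
hexaserine linker is its own span class — it belongs to neither terminus —
and is detected as the maximal serine run immediately after the N-amorphous
block, kept only when it reaches 6 residues.

Inside the core:

1. **A-motifs** are maximal polyalanine runs of ≥ `a_min_run` (default 5)
   residues.
2. Each maximal inter-A interval becomes one motif span, classified
   **R** if its Arg fraction ≥ `r_arg_min_frac` (default 0.15), else **G**
   if its Gly fraction ≥ `g_gly_min_frac` (default 0.30), else `G_OTHER`.
   The thresholds are chosen to separate the two described populations
   (R-motifs ≈ 27% Arg, G-motifs ≈ 54% Gly) with margin on both sides;
   both are parameters.
3. G spans are subtyped by a proximal `GSGAGG` anchor allowed ≤ 2
   mismatches (no anchor → `G_OTHER`) and then binned by length:
   ≤ 18 → G_a, ≥ 22 → G_c, otherwise G_b. Length bins plus a
   mismatch-tolerant anchor stand in for a subtype definition that is
   descriptive rather than formulaic in the literature.
4. Inter-A intervals shorter than 3 residues are merged into the preceding
   span (into the following one at the very start of the core), so noisy
   input cannot create degenerate one-residue motifs. On clean input this
   rule never fires and every A span is a pure, maximal polyalanine run; on
   mutated input a merged span may be impure, which mirrors the
   serine-interrupted polyalanine of other saturniid fibroins.

Spans always tile the protein — concatenating them reconstructs it exactly —
and segmentation is deterministic. Conservation profiles right-pad
same-class motifs with a gap symbol and count column frequencies over
non-gap residues (no alignment is performed; the motifs are anchored at
their proximal ends by construction). Consensus ties break lexicographically.
Tripeptide censuses (GYG, GGY) count overlapping occurrences by default:
`GYGYG` contains two GYG. The Chi-like recombination motif is searched as
`GCTGGTGG` by default but is user-overridable, since the exact sequence is
an assumption.

## Composition, hydropathy, mass, pI

Residue groups are declared once in `compstats`: polar = S T Y C N Q plus
all charged residues; acidic = D E; basic = K R H; nonpolar = the rest.
Hydropathy uses the Kyte–Doolittle scale with a default window of 9
residues (the classic choice; the window is a parameter, and the meaningful
output for repeat proteins is the *alternation* of sign between hydrophobic
A-motifs and polar inter-motifs, which the tests assert). Masses are average
residue masses plus one water, appropriate for gel-scale comparisons.

The isoelectric point solves net charge = 0 by bisection on pH ∈ [0, 14]
to a net-charge tolerance of 1e-4 (stricter than the 1e-3 the tests
require). The net-charge function uses free termini plus D/E/H/C/Y/K/R side
chains with the Bjellqvist pKa set:

| group | D | E | H | C | Y | K | R | N-term | C-term |
|-------|-----|-----|------|-----|------|------|------|--------|--------|
| pKa   | 4.05| 4.45| 5.98 | 9.0 | 10.0 | 10.0 | 12.0 | 7.5    | 3.55   |

The charge function is strictly decreasing in pH, so the root is unique;
the bracket is asserted at every iteration. Reported pI values are
pKa-set-dependent at the ±0.3–0.4 level, which is why the test suite
cross-checks against an independent Bjellqvist implementation with a 0.5
tolerance rather than asserting point values.

## Codon statistics

Usage tables are keyed by RNA codons (GCA/GGU/UCA) because that is how
silk codon-bias tables are conventionally printed; all sequence handling is
DNA internally. Ties for "preferred isocodon" break lexicographically so
output is deterministic. Homocodon runs are counted **in frame** only: the
relevant biology (GCA concatenation within polyalanine tracts) concerns
codons, and an out-of-frame trinucleotide is not a codon. CpG islands use
the classical Gardiner–Garden criteria (window 200 nt, GC ≥ 0.5,
observed/expected CpG ≥ 0.6, all three parameters); qualifying windows are
merged and each merged island is re-scored over its full span.
`CodonUsageTable.from_percentages` reconstructs (fractional) counts from a
published percentage table plus residue totals, which is how the combined
top-isocodon fraction (~47.7% for GCA+GGU+UCA) is recomputed.

## Restriction digestion

Cut positions are single top-strand coordinates (the base after which the
strand parts); overhangs are not modelled. Sites are matched as IUPAC
patterns on both strands with palindromic deduplication; circular molecules
are scanned on the doubled sequence. Complete digests merge the cut sets of
all enzymes (order-independent), and fragment lengths always sum to the
input length — asserted on every result. Partial digestion enumerates all
C(k+2, 2) boundary pairs for k internal cuts, with a 10,000-product cap.
Fragment tables sort descending and group near-equal sizes into gel bands
by single linkage at a 10-bp default resolution (matching the spread of
observed co-migrant groups, e.g. 381/378/375/372 bp), labelling co-migrants
a, b, c… within a band and flagging terminal fragments, whose sizes depend
on the amplicon boundaries rather than the enzyme.

## The synthetic generator

`fibroin.synthetic.generate` emulates the study system: a ~250-nt promoter
with CAAT (−224), silk-gland factor (−137) and TATA (−25) planted on an
AT-rich background; a 27-nt 5′ UTR; exon 1 with 42 coding nt; a 131-nt
intron with canonical GT…AG ends and an exact-count GC content of 21%; and
a stop-initial 78-nt 3′ UTR with AATAAA planted 56 nt after the stop. The
default motif plan is 17 R / 15 G_a / 46 G_b / 5 G_c, interleaved in
seeded-random order with polyalanine runs drawn uniformly from 5–15
residues; the default isocodon table is the published *A. assama* column
for Ala/Gly/Ser and uniform for all other residues. Motif templates are
**synthetic**: written to match the published per-class composition
(GSGAGG anchors, Gly/Tyr-rich G-motifs, an RGD inside the G_c template,
~29% Arg in the R template), not copied from any deposited sequence. The
amorphous termini are drawn from weighted polar-rich alphabets with Ala and
Ser runs capped (so nothing outside the core can mimic an A-motif or the
linker), Cys excluded everywhere except the C-terminus, where exactly 3 are
planted.

A single seeded `numpy` generator drives all randomness; the same seed
reproduces the gene bit for bit. Template mutation (default rate 0) applies
per-residue substitutions to non-A motifs only and never substitutes *to*
alanine, so mutation cannot create or extend a polyalanine run and the
planted A-motif boundaries remain identifiable ground truth. At a 2%
mutation rate the segmenter still recovers ≥ 95% of planted spans exactly
(seeded test).

What the generator does **not** emulate: real motif sequences (only their
statistics), repeat-expansion evolution (unequal crossing-over), splice-site
sequence context beyond GT…AG, methylation, and the PCR-amplicon end
effects that shift terminal restriction-fragment sizes. Passing round-trip
tests therefore demonstrates that the operations are correct and mutually
consistent, not that the default thresholds are optimal for every real
H-fibroin; measurements that are properties of the one deposited record
(overall CDS GC, first-position G fraction, the GYG census of the real
G-motif set) are validated here on constructed or synthetic inputs whose
ground truth pins the same quantity, and can be recomputed on the real
record by pointing `fibroin analyze` (or `gene-check --genbank`) at a local
copy.

## Problem sizes and determinism

The default synthetic protein is ~2,650 aa (a ~8.4-kb gene), the scale of
the real protein; property suites run 1,000 random digests and dozens of
random peptides/sequences per oracle comparison, which keeps the whole test
suite and the acceptance script in the seconds-to-minutes range on one CPU.
Every stochastic test fixes its seed; `scripts/acceptance.py` derives all
randomness from its `--seed` argument.
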