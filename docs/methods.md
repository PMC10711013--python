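# Methods

## Reference models and the translation oracle

A `GeneModel` is a reference contig slice (1-based inclusive external
coordinates, VCF/SAM style) with ordered, non-overlapping CDS intervals
whose total length is a multiple of 3, and whose unmutated translation
contains no internal stop and ends in a stop. Minus-strand genes store the
plus-strand genomic sequence and translate on the reverse complement, as
BRCA1 does in a real reference; the test suite exercises one minus-strand
model throughout.

Haplotypes are built by applying normalized variants right-to-left in
genomic order so earlier edits never shift later coordinates; overlapping
reference footprints are a hard error. Every haplotype base keeps a
genomic anchor (inserted bases inherit the anchor of the base 5' of
them), which yields both the genomic→haplotype coordinate map and the CDS
extraction under arbitrary indels. Translation is codon-by-codon;
`premature_stop` is true iff the first stop precedes the canonical stop
codon, and a haplotype is *functional* only when it is additionally back
in frame at the canonical stop. A variant that deletes the CDS start
reports `premature_stop=True` with `stop_offset=0` by convention.

Splice-disrupting events are out of scope: the reversions this package
targets are exonic, and toy fixtures are single-exon (multi-exon models
are supported by the data structures).

## Variant space

All small variants are reduced to a left-aligned, parsimonious,
VCF-anchored key `(contig, pos, ref, alt)` before any set operation, so
every right-shifted spelling of an indel in a repeat collapses onto one
key (verified exhaustively over homopolymer and dinucleotide-repeat
fixtures). Consensus keeps variants reported by at least `min_callers`
callers — 2 in matched designs, 1 in tumour-only mode, matching common
multi-caller practice on this assay class — with caller sets unioned and
counts taken from a configurable caller priority. Germline subtraction is
a key-level set difference; known pathogenic germline lesions re-enter
the reversion screen only by explicit configuration, never silently.

Read-level recounting inspects CIGAR-aligned reads directly. A read is
eligible for a variant's denominator when it aligns over the anchor base
with at least `max(len(ref), len(alt)) + 1` query bases remaining: that
budget fully determines the carried allele, and makes eligibility
probability identical for reference and alternate reads under uniform
read starts. Counting over the reference footprint instead would
over-sample deletion reads (their reference span is longer by the deleted
length) and under-sample insertion reads; with 100-bp reads and a 21-bp
deletion the inflation is ~20% relative, which the balanced rule removes
(recovered VAFs are unbiased to within Monte-Carlo error in the
acceptance experiment). Zero eligible reads leaves the VAF *undefined*,
deliberately distinct from an observed VAF of 0.

## Reversion engine

Candidates are somatic variants on the lesion's contig within ±200 bp
(panel read lengths bound what is phaseable; configurable), plus any
deletion overlapping the lesion regardless of distance. Classification:

1. exact inverse of the primary → back-mutation;
2. deletion containing the lesion footprint with own net length ≡ 0 mod 3
   → spanning deletion, subject to the translation oracle;
3. otherwise, combined net length ≡ 0 mod 3 → frame-restoring indel,
   subject to the oracle on the `[primary, candidate]` haplotype;
4. anything overlapping the lesion without containing it is an
   unphaseable allele conflict, never a reversion.

Frame restoration additionally requires the primary alone to truncate the
protein — an intact-protein primary (e.g. an in-frame pathogenic
missense) cannot be "restored" by a passenger indel, and no
protein-function scoring beyond translation is attempted. Pairs of
secondary indels jointly restoring the frame (compound reversions) are
considered up to size 2; larger sets are rejected as unphaseable at panel
read lengths.

Phase: `cis_confirmed` needs ≥ 2 reads (default) carrying both alternate
alleles — one read is too error-prone at 0.1–1% per-base error.
Spanning deletions and back-mutations are `implicit_cis` because the
event physically contains or replaces the lesion. When reads spanning
both loci never co-carry the alleles while each allele is seen separately
at least `min_shared` times, the pair is `trans` and excluded from the
report (kept in the audit log). No read spanning both loci yields
`unknown`, not failure.

Tiers partition (support, VAF) exactly as: high = > 10 reads or
VAF > 5% (strict inequality on both); moderate = 6–10 reads; low = 2–5
reads; rejected < 2. The printed ranges of this scheme overlap ambiguously
at 5 reads; the package resolves the boundary as low = 2–5 and
moderate = 6–10, with the VAF clause evaluated first and an undefined VAF
falling back to the reads-only rules.

### Back-mutations and reference-based calling

A haplotype that exactly restores the reference produces reads identical
to reference, so reference-based callers emit no record for it and
read-level recounting cannot separate reverted reads from wild-type
background. The package therefore carries back-mutations as the inverse
record of the primary (`pos=primary.pos, ref=primary.alt,
alt=primary.ref`) — the "restoring allele" — and keeps caller-provided
counts for them instead of recounting. In real data such events surface
through a drop in the lesion's VAF and manual review; the simulator's
pseudo-callers emit the restoring-allele record with binomially sampled
counts to make the pathway testable end to end.

## Simulator

The generator emulates the targeted-panel regime the pipeline is meant
for: ~500X mean coverage (default `depth=500`), tumour purity drawn from
0.25–0.85, implanted subclonal reversions with true allele fraction
`purity × CCF × 0.5` spanning ~0.5%–17%, per-base substitution error
0.1% by default (validity range up to 5%), 100-bp single-end reads.
Allele-level mixture weights: a germline heterozygous lesion is carried
by normal cells too (dosage 0.5 regardless of purity); a somatic lesion
is confined to tumour cells; a reversion at cancer-cell fraction f
converts weight `purity × 0.5 × f` from the lesion haplotype (or from the
wild-type haplotype for trans-placed negative controls, a configuration
switch used to validate phasing specificity).

Reads start uniformly over the slice and truncate at its right edge,
which makes expected per-base depth equal the target away from the left
edge; alignments (CIGARs) are exact by construction because the
generating haplotype is known — the phasing logic needs read
co-occurrence, not mapping realism. Errors are substitutions only; indel
errors would require realignment machinery that is out of scope.
Spanning-deletion events default to 9–30 bp in-frame deletions containing
the lesion; frame-restoring indels are placed ≥ 6 bp downstream and every
implanted event is verified against the translation oracle at generation
time. Pseudo-callers detect each true variant with configurable
sensitivity (default 0.95), draw DP ~ Poisson(depth) and alt counts
binomially at the true VAF, and add Poisson false-positive SNVs at low
VAF; a matched-germline VCF carries the germline lesion plus heterozygous
SNPs to exercise subtraction. Everything is deterministic under a fixed
seed, to the byte, for SAM and VCF alike.

What the simulator does **not** model — and hence what passing tests do
not show about real data: paired-end fragments and fragment-level
phasing, base-quality variation, GC/capture bias, alignment and mapping
artefacts, indel sequencing errors, multi-gene panels (the toy locus is a
single 600-bp gene), and copy-number change (the allele-dosage factor is
fixed at 0.5). Recovery rates measured here are therefore an upper bound
on what identical parameters would achieve on real alignments.

## Purity, triage and summaries

TP53-based purity uses the maximum TP53 VAF (clonal assumption) under
either the diploid-heterozygous (`min(1, 2v)`, capped flag when 2v > 1)
or LOH (`2v/(1+v)`) copy model; absence of a usable TP53 variant yields
an undefined estimate, not zero. Triage encodes the manual-review logic
as an explicit, overridable ruleset; SIFT ≤ 0.05 and PolyPhen ≥ 0.85
follow the standard VEP "deleterious"/"probably damaging" conventions.
ARID1A loss has conflicting reported consequences for PARPi response, so
the default ruleset files it under *tenuous*; the packaged curated table
ships with its categories as originally assigned (ARID1A included among
the potential mechanisms), and cohort counts computed from that table use
the shipped categories. Reversion prevalence divides by the
reversion-eligible (BRCA-mutant) patient count and rounds to the nearest
percent; a zero denominator gives an undefined prevalence.

## Numerical and design choices

- External coordinates 1-based inclusive, internal offsets 0-based
  half-open; conversion happens only at I/O boundaries.
- Consensus output and all report files are sorted on the variant key, so
  identical inputs give byte-identical outputs.
- The acceptance experiments run 100 patients at depth 500 over a 600-bp
  locus (~3,000 reads each), sizes chosen to give tight Monte-Carlo error
  on recovery and bias while keeping the whole suite fast.
- Tier boundaries use strict `>` on the 5% VAF clause; 5% exactly is not
  high-confidence by VAF.
- `min_shared=2` both for cis confirmation and the trans test.

## Known limitations

- Back-mutation VAFs rely on caller-provided counts (see above); they are
  only as good as the caller's own counting.
- Structural-variant reversions beyond simple spanning deletions are not
  called; SV handling is limited to breakpoint region flags.
- Compound reversions are limited to two secondary events.
- Phasing is single-read; fragment-level (read-pair) phasing would extend
  the confirmable distance and is a possible extension.
- The HGVS p. parser covers only the simple forms needed for lollipop
  export (missense, nonsense, frameshift, in-frame del/dup).
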