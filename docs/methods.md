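# Methods

## Scope and data model

`ssrmine` develops SSR (microsatellite) markers from genome sequences that
share one coordinate system — a reference plus consensus sequences of
resequenced lines mapped against it. All in-memory coordinates are 0-based
half-open; GFF3's 1-based inclusive convention is converted only at I/O.
Sequences are restricted to {A,C,G,T,N}; other IUPAC codes are mapped to N on
load (logged), since resequencing consensus sequences routinely contain
ambiguity codes and treating them as errors would discard usable contigs.

## Perfect repeat detection

A perfect SSR is an uninterrupted tandem array of a single motif of length
1–6. Detection thresholds are minimum repeat counts per motif length,
default `{1:10, 2:7, 3:6, 4:5, 5:4, 6:4}` — the MISA-style convention in
which the stated count is the minimum accepted (a 7-copy dinucleotide is a
tract, a 6-copy one is not; boundary tests pin this reading).

The scanner computes, per motif length k, the self-match array
`m[i] = (s[i] == s[i+k])`; each maximal run of matches marks a maximal
k-periodic stretch whose leading whole motif copies form a candidate tract.
This is exact and linear per k. Candidates whose motif is a whole-number
repetition of a shorter motif (ATAT) are suppressed — the locus is reported
once, at the primitive period. Overlaps between remaining candidates of
different motif lengths are resolved deterministically: longer tract wins,
ties go to the smaller motif length, then to the leftmost start; the result
is that no two reported tracts share a base. N never matches anything, so
repeats are not called across N (consensus gaps must not fabricate loci).
Compound repeats are reported as their perfect sub-tracts; no compound
records exist.

Motif labels keep the observed phase (the rotation starting at the tract's
first base) and collapse only reverse complements: AG/CT and GA/TC are
distinct classes, matching repeat-type tables that list them separately. For
*cross-genome merging* a fully canonical group (minimal rotation over both
strands) is used instead, because boundary jitter between genomes shifts the
observed phase of one underlying locus; merging must not split on phase.

The per-tract summary table bins repeat counts into
`<5, 5–7, 8–10, 11–15, 16–20, 21–25, 26–30, 31–40, >40` and reports mean
repeat count and mean tract length (= mean count × motif length) per class.

## Flank uniqueness

Marker-grade loci need flanks that occur once in the genome. Defaults:
300 bp per side; a competing *hit* is any genomic interval aligning to a
flank with identity strictly above 0.90 over more than 0.85 × 300 aligned
columns. The search is an exact 16-mer seed lookup (non-overlapping seeds
across the flank, both strands) followed by ungapped full-flank comparison on
each candidate diagonal. Gapped alignment and e-value statistics are
deliberately out of scope: at 300 bp and a 90 % identity floor, the
identity/coverage thresholds are the binding constraints, and the seeded scan
keeps the package dependency-free. Users who want exact BLAST behavior can
feed 12-column tabular alignments through the `--hits-from` escape hatch,
which applies only the filtering logic. Note the seeded scan can miss
homologs whose mutations are spread so evenly that no 16-mer survives —
near the 90 % boundary this makes the screen slightly permissive compared
with BLAST.

Hits overlapping the flank's own interval by ≥50 % collapse into the single
self-hit, and mutually overlapping hit intervals merge, so staggered
self-alignments are not double-counted. A locus is unique iff both flanks
have exactly one hit. Loci closer than one flank length to a contig end, or
with ≥10 % N in a flank, are dropped before screening (logged). Only flanks
are searched, never the repeat tract itself, which would otherwise hit every
same-motif locus.

## Primer design

One primer pair per unique locus, by exhaustive enumeration over both
flanks. Per-primer box: length 18–27 (optimum 20), GC 20–80 %, Tm 57–63 °C
(optimum 60), mononucleotide runs ≤5, and a minimal self-complementarity
screen (no 8-mer of the primer whose reverse complement also occurs in the
primer). Pair constraint: product 30–500 bp, always spanning the tract
(primers never overlap the repeat). The returned pair minimizes

    |len_f − 20| + |len_r − 20| + 1·(|Tm_f − 60| + |Tm_r − 60|)   [°C weight 1]

with ties broken by smaller product, then leftmost forward primer — fully
deterministic. The search prunes by per-primer penalty but is verified
against brute-force pair enumeration on short flanks in the tests.

Tm is an authored nearest-neighbor calculation with the unified dinucleotide
parameters, terminal AT/GC initiation terms, entropic salt correction
`0.368·(N−1)·ln[Na⁺]` and the `C_T/4` strand-concentration term, at 50 mM
monovalent salt and 50 nM oligo. The tests cross-check it against an
independent NN implementation (biopython's, at matched conditions); exact
thermodynamic parity with any particular Primer3 build is not claimed — the
box constraints, not the third decimal of Tm, are the contract.

## Electronic PCR

A primer binds a site when its 3′-terminal word (default 9 nt) matches with
at most one mismatched position — the "discontiguous word = 1" reading in
which the wildcard may fall anywhere in the word — and the 5′ remainder
aligns with at most 1 mismatch and 1 indel, budgeted per primer. The engine
anchors candidate sites with a wildcard-expanded regex scan and aligns the
tail by a tiny Pareto dynamic program over (mismatch, indel) budgets; a
full-scan DP oracle at every position/strand verifies it in the tests. One
consequence of counting a terminal gap as an ordinary indel: a substitution
at the extreme 5′ base can be absorbed by the indel budget.

Facing site pairs (either primer may be the plus-strand one) within
5 000 bp (`max_product`, bounding the quadratic pairing) become amplicons;
`within_expected_size` means |product − expected| ≤ 100 bp. Specificity
status: `unique` = exactly one amplicon, of expected size; `multi_site` =
two or more amplicons; `no_site` = none — a single amplicon of unexpected
size is also folded into `no_site`, treating "binds, but not as designed" as
an improper binding site.

## Cross-genome merging and polymorphism

Per (contig, canonical motif group), start-sorted tracts join single-linkage
components when consecutive starts lie within the merge window (default
5 kb). A component where every genome appears at most once is one panel
locus. When a genome contributes surplus tracts — a case the distance rule
alone does not resolve — the component holds L loci, L being the maximum
per-genome tract count, and is split at its L−1 largest start gaps, so
nearest tracts stay together; any genome still duplicated inside a piece
keeps the tract nearest the piece's median start and the surplus founds its
own locus. The procedure is deterministic and independent of genome input
order (ids re-derive from coordinates). Window monotonicity (larger window
⇒ no more loci) holds in the regime the rule addresses — distinct loci
spaced beyond the window with one tract per genome each; under same-genome
surpluses the count is governed by the split rule instead.

Alleles are detected tract lengths (bp), not e-PCR product sizes; the
polymorphism census deliberately precedes and exceeds the primered subset.
ABSENT means no tract of the motif group within the window in that genome —
biological absence and missing data (low coverage) are indistinguishable
here, which is why the generator models a low-coverage line simply as an
elevated absence rate. Classes: `monomorphic` (present everywhere, one
length), `length_polymorphic` (≥2 lengths, none absent), `presence_absence`
(≥1 absent, one length), `both`.

PIC is `1 − Σ pᵢ²` over unweighted allele frequencies across the sample
set; monomorphic loci score 0 and k balanced alleles score `1 − 1/k`.

## Region classification and statistics

From GFF3 gene models, every base gets exactly one of six labels with
precedence CDS > 5′-UTR > 3′-UTR > intron > promoter > intergenic (so a base
that is coding in one transcript and promoter of a neighbor counts as CDS —
conservative protein-coding assignment). Promoters are a fixed 2 000 bp
upstream of the transcription start, strand-aware; introns are the gene span
minus its exons; unannotated bases are intergenic. The model is held as one
uint8 label array per contig — exact partition by construction, suited to
the multi-megabase panels this package targets rather than a 2+ Gb genome in
a single call. A tract's region is the region of its *start base*; tracts
are tens of bp and no straddle convention is more defensible, so the
deterministic choice wins.

Mean marker interval is genome size / locus count (kb); the genome size is a
config value (default 2.1 × 10⁹ bp, a maize-scale figure) because locus
counts from partial assemblies would otherwise understate density. All
reported percentages round half-up to two decimals. The funnel report counts
loci per stage (detected → unique flanks → primers → e-PCR-specific →
polymorphic) by motif class, each stage as a percentage of its parent.

## Synthetic panels

The generator emulates a reference-anchored resequencing panel: i.i.d.
uniform ACGT background, scrubbed of accidental near-threshold repeats so
the truth table is exhaustive; planted loci at ≥700 bp spacing with exact
per-genome coordinates; motif-length mix defaulting to the mono-dominated
composition typical of a large cereal genome (58/25/10/2/3/2 % for lengths
1–6); founder repeat counts bounded below by the detection thresholds.
Genome `g1` is the reference (founder alleles, no substitutions, never
absent). Other lines mutate each locus's repeat count with probability 0.30
by a symmetric geometric step (the stepwise mutation model, the standard
microsatellite model), lose it with probability 0.05 (tripled for the last
line when the low-coverage flag is set), and accumulate background
substitutions at 2 × 10⁻³ per base. A fraction (default 0.10) of loci have
their ±350 bp window copied into a spacer tail ≥6 kb away in every genome,
giving the uniqueness screen true negatives at a known rate. Tract
boundaries are pinned (the bases adjacent to a tract can never extend or
re-phase it) so planted coordinates are recoverable exactly. Sparse two-exon
gene models (5′UTR/CDS/intron/CDS/3′UTR, alternating strands) provide a
GFF3 for region statistics. Everything is a pure function of the seed.

What the generator does *not* emulate: repeat-rich, GC-skewed real genome
background, interrupted/compound repeats, alignment and consensus-calling
errors, and coverage-dependent missingness. Passing recovery tests therefore
demonstrate algorithmic correctness under the stated mutation model, not
performance on real resequencing data; `hard_mode` plants near-identical
decoy flank copies to stress the uniqueness screen separately.

## Verification sizes

The test suite and the acceptance script use panels of 2–5 genomes with
25–200 loci on 40–160 kb contigs — large enough that every stage (including
seeded search and e-PCR over hundreds of kilobases) is exercised end to end,
small enough to run in seconds to half a minute. Oracle equivalences run on
200 random 2 kb sequences (detection vs. brute force) and ~20 kb genomes
(e-PCR vs. full-scan DP).

## Known limitations

- Flank screening is ungapped and seed-limited (see above); it is the one
  stage where results can differ from a BLAST-based screen near the
  thresholds.
- Allele lengths come from detection, so two different repeat counts whose
  tract lengths coincide across motifs within one canonical group would not
  be distinguished.
- Region models at whole-chromosome (>100 Mb) scale should be built
  per-chromosome to bound memory.
- e-PCR models sequence match only — no thermodynamic binding, no degenerate
  bases.
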