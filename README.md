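# ssrmine

Genome-wide development of simple sequence repeat (SSR / microsatellite)
markers from whole-genome sequences.

SSRs are tandem arrays of 1–6 bp motifs whose repeat number mutates quickly,
making them multiallelic, co-dominant markers that are easy to score by PCR.
Given a reference genome and a panel of reference-anchored genomes (e.g.
resequencing consensus sequences of inbred lines), `ssrmine` runs the whole
marker-development cascade:

1. **Detection** — every maximal *perfect* repeat tract with at least
   10/7/6/5/4/4 copies for mono- through hexanucleotide motifs (MISA-style
   minima). Motifs are reported in observed phase and grouped into
   strand-collapsed classes (AG/CT, AT, C/G, …).
2. **Flank screening** — 300 bp of flank on each side must be unique in the
   genome: any second region matching a flank with >90 % identity over >85 %
   of its length disqualifies the locus (seeded search, both strands).
3. **Primer design** — one pair per locus under a Primer3-style box
   (18–27 nt, optimum 20; GC 20–80 %; Tm 57–63 °C, optimum 60; product
   30–500 bp spanning the tract), scored by
   `|len−20|_f + |len−20|_r + |Tm−60|_f + |Tm−60|_r` with a
   nearest-neighbor thermodynamic Tm.
4. **Electronic PCR** — a primer binds where its 3′-terminal 9-mer word
   matches (one position may mismatch) and the 5′ remainder aligns with ≤1
   mismatch and ≤1 indel; facing sites give amplicons, and a marker is
   *specific* only if exactly one amplicon lies within ±100 bp of the
   expected product.
5. **Panel comparison** — tracts of the same canonical motif within 5 kb
   across genomes merge into panel loci; each locus is classified as
   monomorphic, length-polymorphic, presence/absence, or both, and PIC
   (`1 − Σ pᵢ²` over allele frequencies) scores marker informativeness.
6. **Statistics** — repeat-class tables, marker density (genome size /
   locus count), genomic-region distribution (CDS, 5′/3′-UTR, intron,
   2 kb promoter, intergenic — precedence-resolved from GFF3), GC content,
   the funnel report and BED density tracks.

A synthetic-panel generator (`ssrmine.simulate`) produces multi-genome
fixtures with planted, mutated SSR loci and a machine-readable truth table,
so the entire pipeline is testable without downloads.

## Worked example

```python
from ssrmine import SimConfig, run_genome, simulate_panel

res = simulate_panel(SimConfig(seed=9, n_genomes=1, n_loci=50, contig_lengths=[80_000]))
run = run_genome(res.genomes[0])
```

Printed by `python examples/develop_markers.py`:

```
genome g1: 93,610 bp
  detected SSR tracts      : 55
  flanks extractable       : 55
  unique flanking sequences: 45
  primer pairs designed    : 45
  e-PCR single-amplicon    : 45

example marker chr1:958:CAG:
  fwd TCGTCACCGCGGAGTGCTCT (Tm 60.25 C, GC 65.0%)
  rev GCGACCCGTAGATCGCTCGC (Tm 60.05 C, GC 70.0%)
  expected product 339 bp
```

55 tracts were detected (50 planted loci plus the copies the generator
plants to create true duplication negatives); the 10 loci inside duplicated
windows fail the flank-uniqueness screen, and every surviving locus yields a
primer pair whose e-PCR amplicon is unique — a finished marker. The other
`examples/` scripts demonstrate repeat-class summaries, cross-genome
polymorphism calling with PIC, and standalone e-PCR.

The same stages are available as a CLI:

```bash
ssrmine simulate --out-dir sim --seed 3 --n-genomes 2 --n-loci 15
ssrmine scan   --fasta sim/g1.fa --out tracts.tsv
ssrmine flanks --tracts tracts.tsv --fasta sim/g1.fa --out flanked.tsv
ssrmine primers --flanked flanked.tsv --out primers.tsv
ssrmine epcr   --primers primers.tsv --fasta sim/g1.fa --out calls.tsv
ssrmine panel  --tracts t_g1.tsv --tracts t_g2.tsv --out panel.tsv
ssrmine stats  --tracts tracts.tsv --fasta sim/g1.fa --gff sim/annotation.gff3 --out-dir stats/
```

Every threshold above lives in one YAML config (`ssrmine.load_config` /
`--config`); the defaults are the published maize screening parameters.

## Limitations

The flank-uniqueness search is a seeded ungapped scan, not BLAST: e-value
statistics and gapped alignment are out of scope (precomputed tabular
alignments can be substituted via `ssrmine flanks --hits-from`). Region
models are held as per-contig label arrays, suited to panels up to tens of
megabases per call. See `docs/methods.md` for the full model description and
design rationale.
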