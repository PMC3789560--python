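"""Run the full marker-development funnel on one genome.

Detection -> 300 bp flank extraction -> genome-wide flank-uniqueness screen
(>90 % identity over >85 % of the flank counts as a competing hit) ->
Primer3-style primer design (18-27 nt, GC 20-80 %, Tm 57-63 degC, product
30-500 bp) -> e-PCR specificity check (3'-anchored 9-mer word, 1 mismatch,
1 indel). Each stage only keeps loci the previous stage passed, so the
printed counts can only shrink: that cascade is the marker funnel.
"""

from ssrmine import SimConfig, run_genome, simulate_panel

res = simulate_panel(SimConfig(seed=9, n_genomes=1, n_loci=50, contig_lengths=[80_000]))
genome = res.genomes[0]

run = run_genome(genome)
print(f"genome {genome.genome_id}: {genome.total_length():,} bp")
print(f"  detected SSR tracts      : {len(run.tracts)}")
print(f"  flanks extractable       : {len(run.flanked)}")
print(f"  unique flanking sequences: {len(run.unique)}")
print(f"  primer pairs designed    : {len(run.primers)}")
print(f"  e-PCR single-amplicon    : {len(run.epcr_unique)}")

lid, pair = next(iter(run.primers.items()))
print(f"\nexample marker {lid}:")
print(f"  fwd {pair.fwd_seq} (Tm {pair.fwd_tm} C, GC {pair.fwd_gc}%)")
print(f"  rev {pair.rev_seq} (Tm {pair.rev_tm} C, GC {pair.rev_gc}%)")
print(f"  expected product {pair.product_len} bp")
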