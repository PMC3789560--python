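"""Electronic PCR as a standalone primer-specificity check.

Plants one amplicon and a decoy copy of it in a random genome and asks where
a primer pair would amplify. A primer binds where its 3'-terminal 9-mer
matches (one mismatched position tolerated) and the 5' remainder aligns with
at most 1 mismatch and 1 indel; facing sites within 5 kb define amplicons.
A marker is specific only if exactly one amplicon matches the expected
product size within 100 bp.
"""

import numpy as np

from ssrmine import GenomeSeq, epcr, revcomp

rng = np.random.default_rng(0)
bases = np.array(list("ACGT"))
bg = "".join(bases[rng.integers(0, 4, 30_000)])

fwd = "GCATCCGATACGTTAGGCTC"
rev_site = "TTGACCGGATACCGGTTCAA"
amplicon = fwd + "CT" * 40 + rev_site  # 120 bp product around a (CT)40 tract
genome_unique = GenomeSeq("demo", [("chr1", bg[:10_000] + amplicon + bg[10_000:])])
genome_dup = GenomeSeq(
    "demo", [("chr1", bg[:10_000] + amplicon + bg[10_000:20_000] + amplicon + bg[20_000:])]
)


class Pair:
    fwd_seq, rev_seq, locus_id = fwd, revcomp(rev_site), "demo_marker"


for name, genome in [("single-copy", genome_unique), ("duplicated", genome_dup)]:
    call = epcr(Pair(), genome, expected_size=len(amplicon))
    sizes = [a.product_len for a in call.amplicons]
    print(f"{name:>12} genome: status={call.status:<10} products={sizes}")
print("\n'unique' means one amplicon of the expected size: a usable marker.")
print("'multi_site' flags primers that would amplify more than one locus.")
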