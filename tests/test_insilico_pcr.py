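import numpy as np
import pytest

from conftest import make_genome, random_dna
from ssrmine.insilico_pcr import EPCRConfig, epcr, epcr_batch, find_binding_sites
from ssrmine.io_formats import GenomeSeq, revcomp

FWD = "ATGCCGTTAGGCATCCGATA"
REV_SITE = "TTGACCGGATACCGGTTCAA"  # forward-strand segment the reverse primer binds


def sub(s, i):
    return s[:i] + ("A" if s[i] != "A" else "C") + s[i + 1 :]


# ---------------------------------------------------------------------------
# Full-scan oracle: at EVERY genome position and strand, check the seed word
# by direct Hamming comparison and align the 5' tail with a plain recursive
# edit search under the separate mismatch/indel budgets. Independent of the
# production regex + Pareto-DP engine.
# ---------------------------------------------------------------------------


def oracle_sites(primer, genome, cfg=None):
    cfg = cfg or EPCRConfig()
    w = cfg.word_size
    hits = set()

    def tail_ok(tail, gseq, anchor, direction):
        # tail given 3'->5' outward from the seed; returns True if alignable
        def rec(i, off, mm, ind):
            if mm > cfg.max_mismatches or ind > cfg.max_indels:
                return False
            if i == len(tail):
                return True
            gi = anchor + off if direction > 0 else anchor - 1 - off
            gchar = gseq[gi] if 0 <= gi < len(gseq) else None
            ok = False
            if gchar is not None:
                ok = ok or rec(i + 1, off + 1, mm + (gchar != tail[i]), ind)
                gi2 = anchor + off + 1 if direction > 0 else anchor - 1 - (off + 1)
                g2 = gseq[gi2] if 0 <= gi2 < len(gseq) else None
                if g2 is not None:
                    ok = ok or rec(i + 1, off + 2, mm + (g2 != tail[i]), ind + 1)
            ok = ok or rec(i + 1, off, mm, ind + 1)
            return ok

        return rec(0, 0, 0, 0)

    for sid, seq in genome.records:
        for strand in ("+", "-"):
            if strand == "+":
                word, tail = primer[-w:], primer[:-w][::-1]
            else:
                rc = revcomp(primer)
                word, tail = rc[:w], rc[w:]
            for p in range(len(seq) - w + 1):
                if sum(a != b for a, b in zip(seq[p : p + w], word)) > cfg.discontig_words:
                    continue
                if strand == "+":
                    if tail_ok(tail, seq, p, -1):
                        hits.add((sid, strand, p + w))  # 3' anchor position
                else:
                    if tail_ok(tail, seq, p + w, +1):
                        hits.add((sid, strand, p))
    return hits


def site_anchors(sites):
    return {(s.seq_id, s.strand, s.end if s.strand == "+" else s.start) for s in sites}


class TestFindBindingSites:
    def test_verbatim_primer_found_with_zero_cost(self, rng):
        g = make_genome(random_dna(rng, 500) + FWD + random_dna(rng, 500))
        (s,) = find_binding_sites(FWD, g)
        assert (s.start, s.end, s.strand, s.mismatches, s.indels) == (500, 520, "+", 0, 0)

    def test_one_interior_substitution_found_two_not(self, rng):
        bg = random_dna(rng, 1000)
        one = make_genome(bg[:500] + sub(FWD, 4) + bg[500:])
        two = make_genome(bg[:500] + sub(sub(FWD, 4), 7) + bg[500:])
        assert len(find_binding_sites(FWD, one)) == 1
        assert find_binding_sites(FWD, two) == []

    def test_word_tolerates_one_substitution_not_two(self, rng):
        bg = random_dna(rng, 1000)
        one = make_genome(bg[:500] + sub(FWD, 14) + bg[500:])  # inside 9-mer word
        two = make_genome(bg[:500] + sub(sub(FWD, 13), 16) + bg[500:])
        assert len(find_binding_sites(FWD, one)) == 1
        assert find_binding_sites(FWD, two) == []

    def test_single_indel_in_tail_found(self, rng):
        bg = random_dna(rng, 1000)
        deleted = make_genome(bg[:500] + FWD[:5] + FWD[6:] + bg[500:])
        inserted = make_genome(bg[:500] + FWD[:5] + "G" + FWD[5:] + bg[500:])
        assert len(find_binding_sites(FWD, deleted)) == 1
        assert len(find_binding_sites(FWD, inserted)) == 1

    def test_minus_strand_site(self, rng):
        g = make_genome(random_dna(rng, 300) + revcomp(FWD) + random_dna(rng, 300))
        (s,) = find_binding_sites(FWD, g)
        assert s.strand == "-" and (s.start, s.end) == (300, 320)

    def test_oracle_equivalence_random_genome(self, rng):
        genome = make_genome(random_dna(rng, 8000))
        for primer in (FWD, REV_SITE, revcomp(FWD)):
            got = site_anchors(find_binding_sites(primer, genome))
            assert got == oracle_sites(primer, genome)

    def test_oracle_equivalence_with_planted_variants(self, rng):
        bg = random_dna(rng, 6000)
        seq = (
            bg[:1000] + FWD + bg[1000:2000] + sub(FWD, 3) + bg[2000:3000]
            + FWD[:5] + FWD[6:] + bg[3000:4000] + revcomp(sub(FWD, 8)) + bg[4000:]
        )
        genome = make_genome(seq)
        assert site_anchors(find_binding_sites(FWD, genome)) == oracle_sites(FWD, genome)

    def test_mismatch_tolerance_monotonicity(self, rng):
        bg = random_dna(rng, 2000)
        seq = bg[:500] + sub(FWD, 4) + bg[500:900] + sub(sub(FWD, 3), 8) + bg[900:]
        genome = make_genome(seq)
        prev: set = set()
        for mm in (0, 1, 2, 3):
            cfg = EPCRConfig(max_mismatches=mm)
            got = site_anchors(find_binding_sites(FWD, genome, cfg))
            assert prev <= got
            prev = got


def _pair(fwd=FWD, rev=None, product=None, marker="m1"):
    class P:
        pass

    p = P()
    p.fwd_seq = fwd
    p.rev_seq = rev if rev is not None else revcomp(REV_SITE)
    p.product_len = product
    p.locus_id = marker
    return p


def _amplicon_genome(rng, insert_len=60):
    bg = random_dna(rng, 3000)
    insert = random_dna(rng, insert_len)
    seq = bg[:1500] + FWD + insert + REV_SITE + bg[1500:]
    expected = len(FWD) + insert_len + len(REV_SITE)
    return make_genome(seq), expected


class TestEpcr:
    def test_single_planted_locus_is_unique(self, rng):
        g, expected = _amplicon_genome(rng)
        call = epcr(_pair(product=expected), g)
        assert call.status == "unique"
        assert call.amplicons[0].product_len == expected

    def test_duplicated_locus_is_multi_site(self, rng):
        g, expected = _amplicon_genome(rng)
        seq = g.seq("c1")
        dup = seq[1400 : 1500 + expected + 100]
        g2 = GenomeSeq("g", [("c1", seq + random_dna(rng, 8000) + dup)])
        call = epcr(_pair(product=expected), g2)
        assert call.status == "multi_site"
        assert len(call.amplicons) >= 2

    def test_absent_primers_give_no_site(self, rng):
        g = make_genome(random_dna(rng, 4000))
        assert epcr(_pair(product=100), g).status == "no_site"

    def test_product_far_from_expected_is_not_specific(self, rng):
        g, expected = _amplicon_genome(rng, insert_len=400)
        call = epcr(_pair(product=expected - 300), g)  # deviation > 100 bp
        assert call.status == "no_site"
        assert len(call.amplicons) == 1 and not call.amplicons[0].within_expected_size

    def test_strand_symmetry(self, rng):
        g, expected = _amplicon_genome(rng)
        g_rc = GenomeSeq("g", [("c1", revcomp(g.seq("c1")))])
        a = epcr(_pair(product=expected), g)
        b = epcr(_pair(product=expected), g_rc)
        assert a.status == b.status == "unique"
        assert a.amplicons[0].product_len == b.amplicons[0].product_len
        total = len(g.seq("c1"))
        assert b.amplicons[0].start == total - a.amplicons[0].end

    def test_batch_summary_and_order_independence(self, rng):
        g, expected = _amplicon_genome(rng)
        seq = g.seq("c1")
        dup = seq[1400 : 1500 + expected + 100]
        genome = GenomeSeq("g", [("c1", seq + random_dna(rng, 8000) + dup)])
        pairs = [
            _pair(product=expected, marker="dup"),
            _pair(fwd=random_dna(rng, 20), rev=random_dna(rng, 20), product=100, marker="absent"),
        ]
        # unique marker: distinct primers, its own contig
        rng2 = np.random.default_rng(99)
        fwd2, rev2_site = random_dna(rng2, 20), random_dna(rng2, 20)
        insert = random_dna(rng2, 60)
        c2 = random_dna(rng2, 1500) + fwd2 + insert + rev2_site + random_dna(rng2, 1500)
        exp2 = 20 + 60 + 20
        genome2 = GenomeSeq("g", [("c1", genome.seq("c1")), ("c2", c2)])
        pairs.append(_pair(fwd=fwd2, rev=revcomp(rev2_site), product=exp2, marker="uni"))
        calls, summary = epcr_batch(pairs, genome2)
        assert summary == {"unique": 1, "multi_site": 1, "no_site": 1}
        calls_rev, summary_rev = epcr_batch(list(reversed(pairs)), genome2)
        assert summary_rev == summary
        assert {c.marker_id: c.status for c in calls} == {c.marker_id: c.status for c in calls_rev}
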