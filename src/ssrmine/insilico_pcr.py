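"""Electronic PCR: locate all genomic amplicons of a primer pair.

A primer binds a genomic site when its 3'-terminal seed word (default 9 nt)
matches with at most ``discontig_words`` mismatched (wildcard) positions, and
the remaining 5' portion aligns with at most ``max_mismatches`` substitutions
and ``max_indels`` indels, budgeted per primer. Both strands are searched.
Facing sites of the two primers within ``max_product`` define an amplicon;
an amplicon is "as expected" when its product length is within
``size_deviation`` of the expected size. A marker is specific (``unique``)
when exactly one expected-size amplicon exists.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

from .io_formats import GenomeSeq, revcomp


@dataclass
class EPCRConfig:
    word_size: int = 9
    discontig_words: int = 1
    size_deviation: int = 100
    max_mismatches: int = 1
    max_indels: int = 1
    max_product: int = 5000

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        for name in ("discontig_words", "size_deviation", "max_mismatches", "max_indels"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class BindingSite:
    """One primer binding site. ``start``/``end`` are the genomic footprint
    (0-based half-open); for a ``+`` site the primer's 3' end is at ``end``,
    for a ``-`` site at ``start``."""

    seq_id: str
    start: int
    end: int
    strand: str
    mismatches: int
    indels: int


@dataclass(frozen=True)
class Amplicon:
    seq_id: str
    start: int
    end: int
    fwd_primer_strand: str
    product_len: int
    mismatches: tuple[int, int]
    indels: tuple[int, int]
    within_expected_size: bool


@dataclass
class SpecificityCall:
    marker_id: str
    status: str  # unique | multi_site | no_site
    amplicons: list[Amplicon] = field(default_factory=list)


def _align_tail(rem: str, genome: str, anchor: int, direction: int, cfg: EPCRConfig):
    """Align the non-seed primer portion against the genome next to the seed.

    ``rem`` is given 3'->5' from the seed outward; ``anchor`` is the genome
    position adjacent to the seed and ``direction`` (+1/-1) the direction in
    which the 5' tail extends. Returns (mismatches, indels, genome_span) of
    the best alignment within budget, or None. Tiny DP over Pareto-optimal
    (mismatch, indel) budgets — budgets are single digits.
    """
    n = len(rem)
    if n == 0:
        return (0, 0, 0)
    # states: dict genome_offset -> set of (mm, ind) after consuming i primer chars
    states: dict[int, set[tuple[int, int]]] = {0: {(0, 0)}}
    for i in range(n):
        nxt: dict[int, set[tuple[int, int]]] = {}

        def push(off: int, mm: int, ind: int) -> None:
            if mm > cfg.max_mismatches or ind > cfg.max_indels:
                return
            bucket = nxt.setdefault(off, set())
            if not any(m <= mm and d <= ind for m, d in bucket):
                bucket.add((mm, ind))

        for off, pairs in states.items():
            # genome char consumed at this offset
            gidx = anchor + off if direction > 0 else anchor - 1 - off
            gchar = genome[gidx] if 0 <= gidx < len(genome) else None
            for mm, ind in pairs:
                if gchar is not None:
                    push(off + 1, mm + (0 if gchar == rem[i] else 1), ind)  # (mis)match
                    # genome insertion: skip one genome char, align to the next
                    g2 = anchor + off + 1 if direction > 0 else anchor - 1 - (off + 1)
                    g2char = genome[g2] if 0 <= g2 < len(genome) else None
                    if g2char is not None:
                        push(off + 2, mm + (0 if g2char == rem[i] else 1), ind + 1)
                push(off, mm, ind + 1)  # primer char unaligned (genome deletion)
        states = nxt
        if not states:
            return None
    best = None
    for off, pairs in states.items():
        for mm, ind in pairs:
            key = (ind, mm)
            if best is None or key < (best[1], best[0]):
                best = (mm, ind, off)
    return best


def _seed_patterns(word: str, wildcards: int) -> str:
    """Regex matching the seed word with up to ``wildcards`` arbitrary positions."""
    if wildcards <= 0:
        return re.escape(word)
    alts = [re.escape(word)]
    for i in range(len(word)):
        alts.append(re.escape(word[:i]) + "." + re.escape(word[i + 1 :]))
    return "|".join(alts)


def find_binding_sites(
    primer: str, genome: GenomeSeq, cfg: EPCRConfig | None = None
) -> list[BindingSite]:
    """All genomic sites where the primer binds under the e-PCR tolerances.

    The 3'-terminal ``word_size``-mer anchors the search (regex scan with up
    to ``discontig_words`` wildcard positions); the 5' remainder is aligned
    with the per-primer mismatch/indel budgets. Both strands are searched.
    """
    cfg = cfg or EPCRConfig()
    if len(primer) <= cfg.word_size:
        raise ValueError("primer must be longer than word_size")
    sites: list[BindingSite] = []
    w = cfg.word_size
    for strand in ("+", "-"):
        if strand == "+":
            word = primer[-w:]
            rem = primer[:-w][::-1]  # 3'->5' outward from seed
        else:
            rc = revcomp(primer)
            word = rc[:w]
            rem = rc[w:]
        pat = re.compile(f"(?=({_seed_patterns(word, cfg.discontig_words)}))")
        for sid, seq in genome.records:
            for m in pat.finditer(seq):
                p = m.start()
                if strand == "+":
                    res = _align_tail(rem, seq, p, -1, cfg)
                    if res is None:
                        continue
                    mm, ind, span = res
                    sites.append(BindingSite(sid, p - span, p + w, "+", mm, ind))
                else:
                    res = _align_tail(rem, seq, p + w, +1, cfg)
                    if res is None:
                        continue
                    mm, ind, span = res
                    sites.append(BindingSite(sid, p, p + w + span, "-", mm, ind))
    # deduplicate sites sharing a 3' anchor (keep fewest indels, then mismatches)
    best: dict[tuple, BindingSite] = {}
    for s in sites:
        anchor = s.end if s.strand == "+" else s.start
        key = (s.seq_id, s.strand, anchor)
        prev = best.get(key)
        if prev is None or (s.indels, s.mismatches) < (prev.indels, prev.mismatches):
            best[key] = s
    return sorted(best.values(), key=lambda s: (s.seq_id, s.start, s.strand))


def epcr(
    pair,
    genome: GenomeSeq,
    cfg: EPCRConfig | None = None,
    expected_size: int | None = None,
    marker_id: str | None = None,
) -> SpecificityCall:
    """Classify a primer pair's genomic specificity.

    ``pair`` needs ``fwd_seq``/``rev_seq`` (and optionally ``locus_id``,
    ``product_len`` used as the expected size). Every facing combination of a
    ``+`` site of one primer and a ``-`` site of the other within
    ``max_product`` is an amplicon. Status: ``unique`` (exactly one amplicon,
    within the expected-size window), ``multi_site`` (two or more amplicons)
    or ``no_site`` (none, or a single amplicon of unexpected size).
    """
    cfg = cfg or EPCRConfig()
    if expected_size is None:
        expected_size = getattr(pair, "product_len", None)
    marker_id = marker_id or getattr(pair, "locus_id", "marker")
    fwd_sites = find_binding_sites(pair.fwd_seq, genome, cfg)
    rev_sites = find_binding_sites(pair.rev_seq, genome, cfg)
    amplicons: list[Amplicon] = []
    for a_sites, b_sites, label in ((fwd_sites, rev_sites, "+"), (rev_sites, fwd_sites, "-")):
        for sa in a_sites:
            if sa.strand != "+":
                continue
            for sb in b_sites:
                if sb.strand != "-" or sb.seq_id != sa.seq_id:
                    continue
                if not (sa.end <= sb.end and 0 < sb.end - sa.start <= cfg.max_product):
                    continue
                product = sb.end - sa.start
                within = expected_size is not None and abs(product - expected_size) <= cfg.size_deviation
                amplicons.append(
                    Amplicon(
                        seq_id=sa.seq_id,
                        start=sa.start,
                        end=sb.end,
                        fwd_primer_strand=label,
                        product_len=product,
                        mismatches=(sa.mismatches, sb.mismatches),
                        indels=(sa.indels, sb.indels),
                        within_expected_size=within,
                    )
                )
    # identical footprints found through both orderings collapse to one
    amplicons = sorted(
        {(a.seq_id, a.start, a.end): a for a in amplicons}.values(),
        key=lambda a: (a.seq_id, a.start),
    )
    if len(amplicons) == 0:
        status = "no_site"
    elif len(amplicons) >= 2:
        status = "multi_site"
    else:
        status = "unique" if amplicons[0].within_expected_size else "no_site"
    return SpecificityCall(marker_id=marker_id, status=status, amplicons=amplicons)


def epcr_batch(
    pairs, genome: GenomeSeq, cfg: EPCRConfig | None = None
) -> tuple[list[SpecificityCall], dict[str, int]]:
    """Run e-PCR for every pair; returns calls plus a status-count summary."""
    cfg = cfg or EPCRConfig()
    calls = [epcr(p, genome, cfg) for p in pairs]
    summary = dict(Counter(c.status for c in calls))
    for status in ("unique", "multi_site", "no_site"):
        summary.setdefault(status, 0)
    return calls, summary
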