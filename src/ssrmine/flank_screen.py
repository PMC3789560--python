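"""Flank extraction and genome-wide flank uniqueness screening.

A marker-grade SSR locus needs two unique flanking sequences (default 300 bp
on each side of the tract) so that primers amplify a single site. Uniqueness
is decided by a seeded homology search against the whole genome: exact k-mer
seeds (default 16 bp) on both strands, ungapped extension over the full flank,
and a hit is any genomic interval matching the flank with identity > 90 % over
> 85 % of the flank length. A locus is unique when each flank finds exactly
one hit — its own location.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass

from .io_formats import GenomeSeq, revcomp
from .ssr_finder import SSRTract

logger = logging.getLogger(__name__)


@dataclass
class FlankConfig:
    flank_len: int = 300
    min_identity: float = 0.90  # hit requires identity strictly greater
    min_coverage: float = 0.85  # fraction of flank_len that must align
    max_hits: int = 1
    seed_len: int = 16

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("identity/coverage fractions must be in (0, 1]")
        if self.flank_len < self.seed_len:
            raise ValueError("flank_len must be >= seed_len")


@dataclass
class FlankedLocus:
    tract: SSRTract
    left_flank: str
    right_flank: str
    unique: bool | None = None
    hit_counts: tuple[int, int] | None = None

    @property
    def locus_id(self) -> str:
        t = self.tract
        return f"{t.seq_id}:{t.start}:{t.motif}"


def extract_flanks(
    tracts: list[SSRTract], genome: GenomeSeq, cfg: FlankConfig | None = None
) -> list[FlankedLocus]:
    """Extract flank_len bp on each side of every tract.

    Loci closer than flank_len to a contig end, or whose flank is >= 10 % N,
    are dropped (logged with the reason).
    """
    cfg = cfg or FlankConfig()
    out: list[FlankedLocus] = []
    lengths = genome.lengths()
    for t in tracts:
        if t.start < cfg.flank_len or t.end + cfg.flank_len > lengths[t.seq_id]:
            logger.info("locus %s:%d dropped: flank truncated by contig end", t.seq_id, t.start)
            continue
        seq = genome.seq(t.seq_id)
        left = seq[t.start - cfg.flank_len : t.start]
        right = seq[t.end : t.end + cfg.flank_len]
        if max(left.count("N"), right.count("N")) >= 0.10 * cfg.flank_len:
            logger.info("locus %s:%d dropped: flank >= 10%% N", t.seq_id, t.start)
            continue
        out.append(FlankedLocus(tract=t, left_flank=left, right_flank=right))
    return out


class GenomeIndex:
    """Exact k-mer position index over the forward strand of a genome."""

    def __init__(self, genome: GenomeSeq, seed_len: int):
        self.genome = genome
        self.seed_len = seed_len
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for sid, seq in genome.records:
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i : i + seed_len]
                if "N" not in kmer:
                    self.index[kmer].append((sid, i))

    def seed_hits(self, query: str) -> set[tuple[str, int]]:
        """Candidate (seq_id, diagonal) pairs for a query on the forward strand."""
        k = self.seed_len
        diags: set[tuple[str, int]] = set()
        for qpos in range(0, len(query) - k + 1, k):
            kmer = query[qpos : qpos + k]
            for sid, gpos in self.index.get(kmer, ()):
                diags.add((sid, gpos - qpos))
        return diags


def _ungapped_hit(
    query: str, genome_seq: str, diag: int, cfg: FlankConfig
) -> tuple[int, int] | None:
    """Identity-filtered ungapped comparison of query placed at offset diag.

    Returns the genomic (start, end) interval of the aligned columns if the
    placement qualifies as a hit, else None.
    """
    g_start = max(diag, 0)
    g_end = min(diag + len(query), len(genome_seq))
    cols = g_end - g_start
    if cols <= cfg.min_coverage * len(query):
        return None
    q = query[g_start - diag : g_end - diag]
    g = genome_seq[g_start:g_end]
    matches = sum(a == b for a, b in zip(q, g))
    if matches <= cfg.min_identity * cols:
        return None
    return (g_start, g_end)


def _flank_hits(
    flank: str,
    flank_interval: tuple[str, int, int],
    genome: GenomeSeq,
    index: GenomeIndex,
    cfg: FlankConfig,
) -> int:
    """Count distinct genomic hits of one flank, collapsing self-alignments.

    Hits on either strand count; hits overlapping the flank's own interval by
    >= 50 % are collapsed into the single self-hit, and mutually overlapping
    hit intervals (>= 50 %) are merged so staggered seeds are not
    double-counted.
    """
    own_sid, own_start, own_end = flank_interval
    intervals: list[tuple[str, int, int]] = []
    for strand, query in (("+", flank), ("-", revcomp(flank))):
        for sid, diag in index.seed_hits(query):
            hit = _ungapped_hit(query, genome.seq(sid), diag, cfg)
            if hit is not None:
                intervals.append((sid, hit[0], hit[1]))
    # merge intervals overlapping >= 50% of the shorter one
    intervals = sorted(set(intervals))
    merged: list[list] = []
    for sid, s, e in intervals:
        if merged:
            psid, ps, pe = merged[-1]
            ov = min(e, pe) - max(s, ps)
            if sid == psid and ov >= 0.5 * min(e - s, pe - ps):
                merged[-1] = [sid, min(s, ps), max(e, pe)]
                continue
        merged.append([sid, s, e])
    count = 0
    self_seen = False
    for sid, s, e in merged:
        ov = min(e, own_end) - max(s, own_start)
        if sid == own_sid and ov >= 0.5 * min(e - s, own_end - own_start):
            self_seen = True
        else:
            count += 1
    return count + (1 if self_seen else 0)


def screen_uniqueness(
    loci: list[FlankedLocus],
    genome: GenomeSeq,
    cfg: FlankConfig | None = None,
    index: GenomeIndex | None = None,
) -> list[FlankedLocus]:
    """Set unique/hit_counts on every locus by seeded genome search.

    A locus is unique iff both flanks have exactly one hit (the self-hit).
    Passing a prebuilt :class:`GenomeIndex` amortizes indexing over calls.
    """
    cfg = cfg or FlankConfig()
    if index is None:
        index = GenomeIndex(genome, cfg.seed_len)
    for locus in loci:
        t = locus.tract
        left_iv = (t.seq_id, t.start - cfg.flank_len, t.start)
        right_iv = (t.seq_id, t.end, t.end + cfg.flank_len)
        lh = _flank_hits(locus.left_flank, left_iv, genome, index, cfg)
        rh = _flank_hits(locus.right_flank, right_iv, genome, index, cfg)
        locus.hit_counts = (lh, rh)
        locus.unique = lh == cfg.max_hits and rh == cfg.max_hits
    return loci


def apply_hit_filter(
    loci: list[FlankedLocus], hits_table, cfg: FlankConfig | None = None
) -> list[FlankedLocus]:
    """Apply only the uniqueness filtering logic to precomputed alignments.

    ``hits_table`` is a pandas DataFrame in 12-column tabular alignment format
    (qseqid, sseqid, pident, length, mismatch, gapopen, qstart, qend, sstart,
    send, evalue, bitscore) where qseqid is "<locus_id>/L" or "<locus_id>/R".
    Identity is filtered at > min_identity (percent) and aligned length at
    > min_coverage x flank_len; a locus is unique iff each flank retains
    exactly one hit.
    """
    cfg = cfg or FlankConfig()
    df = hits_table
    df = df[(df["pident"] > cfg.min_identity * 100) & (df["length"] > cfg.min_coverage * cfg.flank_len)]
    counts = df.groupby("qseqid").size().to_dict()
    for locus in loci:
        lh = counts.get(f"{locus.locus_id}/L", 0)
        rh = counts.get(f"{locus.locus_id}/R", 0)
        locus.hit_counts = (lh, rh)
        locus.unique = lh == cfg.max_hits and rh == cfg.max_hits
    return loci
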