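"""Descriptive statistics: genomic-region classification, density/interval
arithmetic, GC content, polymorphism information content (PIC), the marker
refinement funnel and density-track export.

Region classification partitions every base into exactly one of six labels
(CDS, 5'-UTR, 3'-UTR, intron, promoter, intergenic) from a GFF3 gene
annotation, with overlaps resolved by a fixed precedence order (CDS first) and
promoters taken as a fixed window (default 2 kb) upstream of each gene's
transcription start, strand-aware.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .io_formats import GFFFeature
from .ssr_finder import SSRTract, classify_motif

logger = logging.getLogger(__name__)

REGION_LABELS = ["CDS", "five_prime_UTR", "three_prime_UTR", "intron", "promoter", "intergenic"]


@dataclass
class RegionConfig:
    promoter_len: int = 2000  # bp upstream of the transcription start site
    precedence: list[str] = field(default_factory=lambda: list(REGION_LABELS))

    def __post_init__(self) -> None:
        if sorted(self.precedence) != sorted(REGION_LABELS):
            raise ValueError("precedence must be a permutation of the six region labels")


@dataclass
class DensityConfig:
    genome_size: float = 2.1e9  # bp assumed for interval statistics


def round2(x: float) -> float:
    """Round half-up to 2 decimals (table-reporting convention)."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class RegionModel:
    """Per-contig base-resolution region labels (precedence-resolved).

    Internally one uint8 numpy array per contig; exact partition by
    construction. Suited to the multi-megabase panels this package targets,
    not to whole 2+ Gb genomes in a single call.
    """

    def __init__(self, labels: dict[str, np.ndarray]):
        self.labels = labels

    def label_at(self, seq_id: str, pos: int) -> str:
        return REGION_LABELS[self.labels[seq_id][pos]]

    def region_lengths(self) -> dict[str, int]:
        out = {lab: 0 for lab in REGION_LABELS}
        for arr in self.labels.values():
            counts = np.bincount(arr, minlength=len(REGION_LABELS))
            for i, lab in enumerate(REGION_LABELS):
                out[lab] += int(counts[i])
        return out

    def total_length(self) -> int:
        return sum(len(a) for a in self.labels.values())


def build_region_model(
    gff: list[GFFFeature], genome_lengths: dict[str, int], cfg: RegionConfig | None = None
) -> RegionModel:
    """Derive the six-way region partition from a GFF3 feature list.

    Promoter = promoter_len bp upstream of the transcription start (mirrored
    on the minus strand); introns = gene span minus exons; any base in no
    feature is intergenic; overlaps resolve by precedence (default CDS >
    5'-UTR > 3'-UTR > intron > promoter > intergenic).
    """
    cfg = cfg or RegionConfig()
    for f in gff:
        if f.seq_id in genome_lengths and f.end > genome_lengths[f.seq_id]:
            raise ValueError(
                f"feature {f.feature_id or f.type} extends beyond contig {f.seq_id} "
                f"({f.end} > {genome_lengths[f.seq_id]})"
            )
    intergenic_code = REGION_LABELS.index("intergenic")
    labels = {
        sid: np.full(n, intergenic_code, dtype=np.uint8) for sid, n in genome_lengths.items()
    }

    genes = [f for f in gff if f.type == "gene"]
    mrna_parent = {f.feature_id: f.parent for f in gff if f.type == "mRNA" and f.feature_id}
    by_gene: dict[str, dict[str, list[tuple[int, int]]]] = {}

    def gene_of(feature: GFFFeature) -> str | None:
        p = feature.parent
        # walk one level: exon/CDS/UTR -> mRNA -> gene
        if p in mrna_parent:
            return mrna_parent[p]
        return p

    for f in gff:
        if f.type in ("CDS", "five_prime_UTR", "three_prime_UTR", "exon"):
            g = gene_of(f)
            if g is None:
                continue
            by_gene.setdefault(g, {}).setdefault(f.type, []).append((f.start - 1, f.end))

    # paint in reverse precedence so higher precedence overwrites
    paint: list[tuple[str, str, int, int]] = []  # (label, seq_id, start0, end0)
    for gene in genes:
        sid = gene.seq_id
        if sid not in labels:
            continue
        gstart0, gend0 = gene.start - 1, gene.end
        if gene.strand == "-":
            prom = (gend0, min(gend0 + cfg.promoter_len, genome_lengths[sid]))
        else:
            prom = (max(gstart0 - cfg.promoter_len, 0), gstart0)
        paint.append(("promoter", sid, prom[0], prom[1]))
        parts = by_gene.get(gene.feature_id, {})
        exons = parts.get("exon") or [
            iv for k in ("CDS", "five_prime_UTR", "three_prime_UTR") for iv in parts.get(k, [])
        ]
        # introns: gene span minus exon union
        exon_mask = np.zeros(gend0 - gstart0, dtype=bool)
        for s, e in exons:
            exon_mask[max(s - gstart0, 0) : max(e - gstart0, 0)] = True
        intron_runs = _mask_runs(~exon_mask, offset=gstart0)
        for s, e in intron_runs:
            paint.append(("intron", sid, s, e))
        for label in ("three_prime_UTR", "five_prime_UTR", "CDS"):
            for s, e in parts.get(label, []):
                paint.append((label, sid, s, e))

    order = {lab: i for i, lab in enumerate(cfg.precedence)}
    paint.sort(key=lambda p: -order[p[0]])  # lowest precedence painted first
    for label, sid, s, e in paint:
        labels[sid][s:e] = REGION_LABELS.index(label)
    return RegionModel(labels)


def _mask_runs(mask: np.ndarray, offset: int = 0) -> list[tuple[int, int]]:
    """Contiguous True runs of a boolean mask as (start, end) with offset added."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.where(diff == 1)[0] + 1)
    ends = list(np.where(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return [(int(s) + offset, int(e) + offset) for s, e in zip(starts, ends)]


def assign_regions(tracts: list[SSRTract], model: RegionModel) -> dict[SSRTract, str]:
    """Region label per tract, decided by the tract's start base."""
    return {t: model.label_at(t.seq_id, t.start) for t in tracts}


def region_table(tracts: list[SSRTract], model: RegionModel) -> pd.DataFrame:
    """Per-region SSR count, mean interval (kb), mean tract length and GC%."""
    assign = assign_regions(tracts, model)
    lengths = model.region_lengths()
    rows = []
    for label in REGION_LABELS:
        members = [t for t, lab in assign.items() if lab == label]
        row = {
            "region": label,
            "count": len(members),
            "region_bp": lengths[label],
            "interval_kb": round2(lengths[label] / len(members) / 1000.0) if members else float("nan"),
            "mean_length_bp": round2(sum(t.length for t in members) / len(members)) if members else float("nan"),
            "gc_pct": round2(
                sum(gc_content(t.tract_seq) for t in members) / len(members)
            ) if members else float("nan"),
        }
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def interval_stats(count: int, cfg: DensityConfig | None = None) -> float:
    """Mean interval between loci in kb: genome_size / count, 2-decimal rounded."""
    cfg = cfg or DensityConfig()
    if count <= 0:
        raise ValueError("count must be > 0")
    return round2(cfg.genome_size / count / 1000.0)


def gc_content(seq: str) -> float:
    """GC percentage of a sequence (N excluded from the denominator)."""
    acgt = sum(c in "ACGT" for c in seq)
    if acgt == 0:
        return 0.0
    return 100.0 * sum(c in "GC" for c in seq) / acgt


def pic(freqs) -> float:
    """Polymorphism information content: 1 - sum(p_i^2) over allele frequencies."""
    freqs = list(freqs)
    if any(p < 0 for p in freqs):
        raise ValueError("allele frequencies must be non-negative")
    if abs(sum(freqs) - 1.0) > 1e-9:
        raise ValueError(f"allele frequencies must sum to 1 (got {sum(freqs)})")
    return 1.0 - sum(p * p for p in freqs)


def pic_from_alleles(alleles) -> float:
    """PIC from a list of observed allele values (missing entries = None, skipped)."""
    obs = [a for a in alleles if a is not None]
    if not obs:
        raise ValueError("no observed alleles")
    n = len(obs)
    counts: dict = {}
    for a in obs:
        counts[a] = counts.get(a, 0) + 1
    return pic([c / n for c in counts.values()])


def percent(numerator: float, denominator: float, decimals: int = 2) -> float:
    """Share as a percentage, rounded half-up."""
    if denominator == 0:
        raise ValueError("denominator must be nonzero")
    x = 100.0 * numerator / denominator
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def funnel_report(
    all_tracts: list[SSRTract],
    unique_loci,
    designed,
    epcr_unique,
    polymorphic,
) -> pd.DataFrame:
    """Marker-refinement funnel by motif class.

    Stages: all detected tracts -> unique-flank loci -> primer-designed ->
    e-PCR-specific -> polymorphic. Each stage's percentage is taken against
    its parent stage's count (2-decimal, half-up). Inputs after the first are
    collections whose elements expose the underlying tract via ``.tract`` or
    are tracts themselves.
    """

    def tract_of(x) -> SSRTract:
        return x if isinstance(x, SSRTract) else x.tract

    stages = {
        "all_ssrs": [tract_of(x) for x in all_tracts],
        "unique_flanks": [tract_of(x) for x in unique_loci],
        "primers_designed": [tract_of(x) for x in designed],
        "epcr_unique": [tract_of(x) for x in epcr_unique],
        "polymorphic": [tract_of(x) for x in polymorphic],
    }
    classes = sorted({classify_motif(t.motif) for t in stages["all_ssrs"]})
    rows = []
    names = list(stages)
    for cls in classes + ["total"]:
        row: dict = {"motif_class": cls}
        parent_count = None
        for name in names:
            members = [
                t for t in stages[name] if cls == "total" or classify_motif(t.motif) == cls
            ]
            count = len(members)
            row[name] = count
            row[f"{name}_pct"] = (
                100.0 if parent_count is None else (percent(count, parent_count) if parent_count else float("nan"))
            )
            parent_count = count
        rows.append(row)
    df = pd.DataFrame(rows).set_index("motif_class")
    return df


def motif_class_shares(tracts: list[SSRTract]) -> pd.DataFrame:
    """Share of each motif class among the given tracts (percentages sum to ~100)."""
    classes: dict[str, int] = {}
    for t in tracts:
        classes[classify_motif(t.motif)] = classes.get(classify_motif(t.motif), 0) + 1
    total = len(tracts)
    rows = [
        {"motif_class": c, "count": n, "share_pct": percent(n, total)}
        for c, n in sorted(classes.items())
    ]
    return pd.DataFrame(rows).set_index("motif_class")


def density_track(
    tracts: list[SSRTract], genome_lengths: dict[str, int], window: int = 10000
) -> pd.DataFrame:
    """Per-window SSR counts as a BED-style table (0-based half-open)."""
    rows = []
    by_seq: dict[str, list[int]] = {}
    for t in tracts:
        by_seq.setdefault(t.seq_id, []).append(t.start)
    for sid, length in sorted(genome_lengths.items()):
        starts = np.array(sorted(by_seq.get(sid, [])))
        for ws in range(0, length, window):
            we = min(ws + window, length)
            n = int(np.searchsorted(starts, we) - np.searchsorted(starts, ws))
            rows.append({"seq_id": sid, "start": ws, "end": we, "count": n})
    return pd.DataFrame(rows)


def write_density_bed(track: pd.DataFrame, path) -> None:
    track.to_csv(path, sep="\t", header=False, index=False)


def overlap_marker_sets(
    a: list[tuple[str, int, int]], b: list[tuple[str, int, int]], slop: int = 0
) -> list[tuple[int, int]]:
    """Generic coordinate-overlap comparison of two marker sets.

    Markers are (seq_id, start, end) intervals; returns index pairs (i, j)
    where a[i] and b[j] overlap after padding each by ``slop`` bp.
    """
    out = []
    by_seq: dict[str, list[tuple[int, int, int]]] = {}
    for j, (sid, s, e) in enumerate(b):
        by_seq.setdefault(sid, []).append((s, e, j))
    for i, (sid, s, e) in enumerate(a):
        for bs, be, j in by_seq.get(sid, ()):
            if s - slop < be and bs < e + slop:
                out.append((i, j))
    return out
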