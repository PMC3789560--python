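"""Cross-genome merging of SSR calls into panel loci and polymorphism calling.

Panel genomes are reference-anchored consensus sequences, so the same locus
sits at nearly the same coordinate in every genome. Tracts of the same
canonical motif group (reverse complement and cyclic rotation collapsed) whose
start positions fall within a merge window (default 5 kb) are combined into
one panel locus by single-linkage clustering; each genome contributes at most
one allele per locus, with surplus same-genome tracts founding a new locus.
A locus is length-polymorphic when present genomes disagree on tract length,
shows presence/absence variation when at least one genome lacks it, and is
monomorphic when present everywhere with one length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .ssr_finder import SSRTract, canonical_motif_group, classify_motif

ABSENT = "ABSENT"


@dataclass
class MergeConfig:
    window: int = 5000
    require_same_motif: bool = True  # canonical motif-group equality

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be > 0")


@dataclass
class PanelLocus:
    locus_id: str
    seq_id: str
    ref_start: int
    ref_end: int
    motif_class: str
    alleles: dict[str, tuple[int, int] | str]  # genome_id -> (tract_len, repeats) | ABSENT
    poly_class: str | None = None
    n_present: int = 0
    members: list[SSRTract] = field(default_factory=list)

    def present_lengths(self) -> list[int]:
        return [v[0] for v in self.alleles.values() if v != ABSENT]


def merge_panel(
    tract_sets: dict[str, list[SSRTract]], cfg: MergeConfig | None = None
) -> list[PanelLocus]:
    """Merge per-genome tract lists into panel loci on reference coordinates.

    Per (seq_id, motif group), start-sorted tracts are first joined into
    single-linkage components (consecutive starts within ``window``). A
    component in which no genome appears twice is one locus. When a genome
    contributes surplus tracts the component holds several loci: with L the
    maximum per-genome tract count, the component is split at its L-1 largest
    start gaps (nearest tracts stay together), and any genome still duplicated
    within a piece keeps the tract nearest the piece's median start while the
    surplus founds its own locus. Fully deterministic and input
    order-independent (the sweep order is sorted). Every genome in
    ``tract_sets`` gets an allele slot in every locus (ABSENT when it
    contributed no tract).
    """
    cfg = cfg or MergeConfig()
    panel_genomes = sorted(tract_sets)
    groups: dict[tuple[str, str], list[SSRTract]] = {}
    for gid in panel_genomes:
        for t in tract_sets[gid]:
            key = (t.seq_id, canonical_motif_group(t.motif) if cfg.require_same_motif else "")
            groups.setdefault(key, []).append(t)
    loci: list[PanelLocus] = []
    for (seq_id, _group), tracts in sorted(groups.items()):
        tracts.sort(key=lambda t: (t.start, t.genome_id))
        components: list[list[SSRTract]] = []
        for t in tracts:
            if components and t.start - components[-1][-1].start <= cfg.window:
                components[-1].append(t)
            else:
                components.append([t])
        clusters: list[list[SSRTract]] = []
        for comp in components:
            clusters.extend(_split_component(comp))
        for members in clusters:
            alleles: dict[str, tuple[int, int] | str] = {g: ABSENT for g in panel_genomes}
            for m in members:
                alleles[m.genome_id] = (m.length, m.repeat_count)
            ref_start = min(m.start for m in members)
            ref_end = max(m.end for m in members)
            loci.append(
                PanelLocus(
                    locus_id=f"{seq_id}:{ref_start}:{canonical_motif_group(members[0].motif)}",
                    seq_id=seq_id,
                    ref_start=ref_start,
                    ref_end=ref_end,
                    motif_class=classify_motif(members[0].motif),
                    alleles=alleles,
                    members=list(members),
                )
            )
    for locus in loci:
        classify_polymorphism(locus, len(panel_genomes))
    loci.sort(key=lambda l: (l.seq_id, l.ref_start, l.locus_id))
    return loci


def _split_component(comp: list[SSRTract]) -> list[list[SSRTract]]:
    """Split one single-linkage component into loci (see merge_panel)."""
    counts: dict[str, int] = {}
    for t in comp:
        counts[t.genome_id] = counts.get(t.genome_id, 0) + 1
    n_loci = max(counts.values())
    if n_loci == 1:
        return [comp]
    # cut at the n_loci - 1 largest start gaps (ties: leftmost gap)
    gaps = sorted(
        range(len(comp) - 1),
        key=lambda i: (-(comp[i + 1].start - comp[i].start), i),
    )[: n_loci - 1]
    cuts = sorted(gaps)
    pieces: list[list[SSRTract]] = []
    prev = 0
    for c in cuts:
        pieces.append(comp[prev : c + 1])
        prev = c + 1
    pieces.append(comp[prev:])
    out: list[list[SSRTract]] = []
    for piece in pieces:
        starts = sorted(t.start for t in piece)
        median = starts[len(starts) // 2]
        keep: dict[str, SSRTract] = {}
        surplus: list[SSRTract] = []
        for t in piece:
            prev_t = keep.get(t.genome_id)
            if prev_t is None:
                keep[t.genome_id] = t
            elif abs(t.start - median) < abs(prev_t.start - median):
                surplus.append(prev_t)
                keep[t.genome_id] = t
            else:
                surplus.append(t)
        out.append(sorted(keep.values(), key=lambda t: (t.start, t.genome_id)))
        out.extend([s] for s in surplus)
    return out


def classify_polymorphism(locus: PanelLocus, panel_size: int) -> str:
    """Set and return the locus's polymorphism class.

    monomorphic: present in all genomes with one tract length;
    length_polymorphic: >= 2 distinct lengths among present genomes, none
    absent; presence_absence: >= 1 genome absent, present lengths equal;
    both: length differences and absence together.
    """
    lengths = locus.present_lengths()
    locus.n_present = len(lengths)
    n_absent = panel_size - locus.n_present
    length_poly = len(set(lengths)) >= 2
    if n_absent == 0:
        locus.poly_class = "length_polymorphic" if length_poly else "monomorphic"
    else:
        locus.poly_class = "both" if length_poly else "presence_absence"
    return locus.poly_class


def is_polymorphic(locus: PanelLocus) -> bool:
    return locus.poly_class in ("length_polymorphic", "presence_absence", "both")


def common_loci(loci: list[PanelLocus], panel_size: int) -> list[PanelLocus]:
    """Loci detected in every panel genome."""
    return [l for l in loci if l.n_present == panel_size]


def panel_table(loci: list[PanelLocus]) -> pd.DataFrame:
    """One row per locus, one tract-length column per genome (ABSENT as '.')."""
    genomes = sorted(loci[0].alleles) if loci else []
    rows = []
    for l in loci:
        row = {
            "locus_id": l.locus_id,
            "seq_id": l.seq_id,
            "ref_start": l.ref_start,
            "ref_end": l.ref_end,
            "motif_class": l.motif_class,
            "poly_class": l.poly_class,
            "n_present": l.n_present,
        }
        for g in genomes:
            a = l.alleles[g]
            row[g] = "." if a == ABSENT else a[0]
        rows.append(row)
    return pd.DataFrame(rows)
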