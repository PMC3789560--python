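"""Synthetic multi-genome SSR panels with a machine-readable truth table.

The generator emulates the structure of a reference-anchored resequencing
panel: one reference genome plus consensus genomes of further lines, each
carrying planted perfect SSR loci whose repeat counts mutate between lines
(symmetric geometric steps, the stepwise mutation model), may be absent in a
line, and whose flanks accumulate substitutions. One line can be flagged
low-coverage (elevated absence rate), mimicking a wild relative that maps
poorly to the reference. A fraction of loci have their flanking window
duplicated elsewhere in every genome so the flank-uniqueness screen has true
negatives. Background sequence is i.i.d. uniform ACGT, scrubbed of accidental
repeats so the truth table is exhaustive.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenomeSeq, GFFFeature, write_fasta, write_gff3
from .panel_compare import ABSENT
from .ssr_finder import DEFAULT_MIN_REPEATS

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    n_genomes: int = 5
    contig_lengths: list[int] = field(default_factory=lambda: [160_000, 160_000])
    n_loci: int = 200
    #: sampling probabilities for motif lengths 1..6 (genome-wide SSR
    #: composition is dominated by mono- and dinucleotide repeats)
    motif_length_mix: list[float] = field(
        default_factory=lambda: [0.58, 0.25, 0.10, 0.02, 0.03, 0.02]
    )
    #: founder repeat-count range per motif length; lower bounds sit at the
    #: detection thresholds so every planted locus is detectable
    repeat_count_range: dict[int, tuple[int, int]] = field(
        default_factory=lambda: {1: (10, 24), 2: (7, 20), 3: (6, 14), 4: (5, 11), 5: (4, 9), 6: (4, 8)}
    )
    p_absent: float = 0.05
    p_length_mut: float = 0.30
    flank_snp_rate: float = 0.002
    duplication_rate: float = 0.10
    gene_model_density: float = 0.05  # genes per kb of contig
    low_coverage_genome: bool = True  # last genome gets 3x p_absent
    hard_mode: bool = False  # plant near-identical decoy flank copies
    min_spacing: int = 700

    def __post_init__(self) -> None:
        for p in (self.p_absent, self.p_length_mut, self.flank_snp_rate, self.duplication_rate):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if abs(sum(self.motif_length_mix) - 1.0) > 1e-9:
            raise ValueError("motif_length_mix must sum to 1")
        for k, (lo, hi) in self.repeat_count_range.items():
            if lo < DEFAULT_MIN_REPEATS[k]:
                raise ValueError(f"repeat range for motif length {k} below detection threshold")


@dataclass
class SimResult:
    genomes: list[GenomeSeq]
    gff: list[GFFFeature]
    truth: pd.DataFrame  # one row per planted locus

    @property
    def genome_ids(self) -> list[str]:
        return [g.genome_id for g in self.genomes]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


# disruption thresholds one repeat below detection, so background never
# reaches a callable tract even after a single boundary coincidence
_SCRUB = {1: 8, 2: 6, 3: 5, 4: 4, 5: 3, 6: 3}


def _scrub_repeats(seq: str, rng: np.random.Generator) -> str:
    """Break any near-threshold repeat run in a background sequence."""
    s = list(seq)
    for _ in range(6):
        dirty = False
        text = "".join(s)
        for k, min_rep in _SCRUB.items():
            for m in re.finditer(r"([ACGT]{%d})\1{%d,}" % (k, min_rep - 1), text):
                mid = (m.start() + m.end()) // 2
                old = s[mid]
                choices = [b for b in "ACGT" if b != old]
                s[mid] = choices[rng.integers(0, 3)]
                dirty = True
        if not dirty:
            break
    return "".join(s)


def _mutate_background(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    positions = rng.choice(n, size=k, replace=False)
    s = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(0, 3)]
    return "".join(s)


def _geometric_step(rng: np.random.Generator) -> int:
    """Symmetric geometric step size (stepwise mutation model), >= 1."""
    step = rng.geometric(0.6)
    return int(step) if rng.random() < 0.5 else -int(step)


def _pick_motif(rng: np.random.Generator, k: int) -> str:
    """A primitive motif of length k (not a repetition of a shorter motif)."""
    while True:
        m = _random_seq(rng, k)
        if k == 1:
            return m
        if all(m != m[:p] * (k // p) for p in range(1, k) if k % p == 0):
            return m


def simulate_panel(cfg: SimConfig | None = None) -> SimResult:
    """Generate a panel of genomes with planted SSR loci and its truth table.

    Genome ``g1`` is the founder/reference: founder alleles, no flank SNPs,
    never absent. Genomes ``g2..gN`` carry per-locus repeat-count mutations
    (probability ``p_length_mut``), absences (``p_absent``; tripled for the
    last genome when ``low_coverage_genome``), and background substitutions at
    ``flank_snp_rate``. A ``duplication_rate`` fraction of loci have their
    +-350 bp window copied into a spacer tail appended to their contig, in
    every genome.

    Raises ValueError when the contigs cannot hold ``n_loci`` at
    ``min_spacing`` bp spacing.
    """
    cfg = cfg or SimConfig()
    rng = np.random.default_rng(cfg.seed)
    genome_ids = [f"g{i + 1}" for i in range(cfg.n_genomes)]

    # --- allocate loci to contigs proportionally ---------------------------
    total_len = sum(cfg.contig_lengths)
    loci_per_contig = [int(round(cfg.n_loci * L / total_len)) for L in cfg.contig_lengths]
    while sum(loci_per_contig) > cfg.n_loci:
        loci_per_contig[int(np.argmax(loci_per_contig))] -= 1
    while sum(loci_per_contig) < cfg.n_loci:
        loci_per_contig[int(np.argmin(loci_per_contig))] += 1

    margin = 400  # clearance at contig ends so flanks are never truncated
    max_tract = max(hi * k for k, (lo, hi) in cfg.repeat_count_range.items())
    truth_rows: list[dict] = []
    # per contig: list of (background segments, locus descriptors)
    contig_plans = []
    for ci, (length, n_here) in enumerate(zip(cfg.contig_lengths, loci_per_contig)):
        usable = length - 2 * margin
        slot = usable // max(n_here, 1)
        if n_here and slot < cfg.min_spacing + max_tract:
            raise ValueError(
                f"cannot place {n_here} loci in contig of {length} bp at "
                f">= {cfg.min_spacing} bp spacing"
            )
        seq_id = f"chr{ci + 1}"
        loci = []
        for j in range(n_here):
            k = int(rng.choice(np.arange(1, 7), p=cfg.motif_length_mix))
            lo, hi = cfg.repeat_count_range[k]
            reps = int(rng.integers(lo, hi + 1))
            motif = _pick_motif(rng, k)
            jitter_max = max(slot - cfg.min_spacing - max_tract, 1)
            pos = margin + j * slot + int(rng.integers(0, jitter_max))
            loci.append({"seq_id": seq_id, "pos": pos, "motif": motif, "reps": reps})
        contig_plans.append((seq_id, length, loci))

    # --- per-genome allele draws ------------------------------------------
    all_loci = [loc for _, _, loci in contig_plans for loc in loci]
    n_dup = int(round(cfg.duplication_rate * len(all_loci)))
    dup_idx = set(rng.choice(len(all_loci), size=n_dup, replace=False).tolist()) if n_dup else set()
    for i, loc in enumerate(all_loci):
        loc["index"] = i
        loc["duplicated"] = i in dup_idx
        loc["alleles"] = {}
        for gi, gid in enumerate(genome_ids):
            if gi == 0:
                loc["alleles"][gid] = loc["reps"]
                continue
            p_abs = cfg.p_absent
            if cfg.low_coverage_genome and gi == cfg.n_genomes - 1:
                p_abs = min(3 * cfg.p_absent, 1.0)
            if rng.random() < p_abs:
                loc["alleles"][gid] = None
            elif rng.random() < cfg.p_length_mut:
                k = len(loc["motif"])
                reps = loc["reps"] + _geometric_step(rng)
                loc["alleles"][gid] = max(reps, DEFAULT_MIN_REPEATS[k])
            else:
                loc["alleles"][gid] = loc["reps"]

    # --- founder background segments (shared across genomes) ---------------
    founder_segments = []  # per contig: list of scrubbed background strings
    for seq_id, length, loci in contig_plans:
        segs = []
        prev = 0
        for loc in loci:
            seg = _scrub_repeats(_random_seq(rng, loc["pos"] - prev), rng)
            motif = loc["motif"]
            # pin tract boundaries: no rotated left extension, no right copy
            if seg:
                if seg[-1] == motif[-1]:
                    seg = seg[:-1] + ("C" if motif[-1] != "C" else "G")
            loc["left_boundary_fix"] = seg[-1] if seg else ""
            segs.append(seg)
            prev = loc["pos"] + len(motif) * loc["reps"]
        tail = _scrub_repeats(_random_seq(rng, length - prev), rng)
        segs.append(tail)
        founder_segments.append(segs)

    # fix right boundary of each tract: first char of following segment must
    # not extend the repeat
    for (seq_id, length, loci), segs in zip(contig_plans, founder_segments):
        for j, loc in enumerate(loci):
            nxt = segs[j + 1]
            if nxt and nxt[0] == loc["motif"][0]:
                repl = "C" if loc["motif"][0] != "C" else "G"
                segs[j + 1] = repl + nxt[1:]
        _founder_contig(loci, segs)  # sets founder_start on every locus

    # --- assemble genomes ---------------------------------------------------
    genomes: list[GenomeSeq] = []
    per_genome_starts: dict[str, dict[int, int | None]] = {g: {} for g in genome_ids}
    for gi, gid in enumerate(genome_ids):
        records = []
        for (seq_id, length, loci), segs in zip(contig_plans, founder_segments):
            parts = []
            cursor = 0
            for j, loc in enumerate(loci):
                seg = segs[j] if gi == 0 else _mutate_background(segs[j], cfg.flank_snp_rate, rng)
                # re-pin tract boundaries mutation may have broken, so planted
                # coordinates stay exact in every genome
                if seg and seg[-1] == loc["motif"][-1]:
                    seg = seg[:-1] + ("C" if loc["motif"][-1] != "C" else "G")
                if j > 0 and seg and seg[0] == loci[j - 1]["motif"][0]:
                    seg = ("C" if loci[j - 1]["motif"][0] != "C" else "G") + seg[1:]
                parts.append(seg)
                cursor += len(seg)
                reps = loc["alleles"][gid]
                if reps is None:
                    filler = _scrub_repeats(
                        _random_seq(rng, len(loc["motif"]) * loc["reps"]), rng
                    )
                    parts.append(filler)
                    per_genome_starts[gid][loc["index"]] = None
                    cursor += len(filler)
                else:
                    tract = loc["motif"] * reps
                    per_genome_starts[gid][loc["index"]] = cursor
                    parts.append(tract)
                    cursor += len(tract)
            tail = segs[-1] if gi == 0 else _mutate_background(segs[-1], cfg.flank_snp_rate, rng)
            if loci and tail and tail[0] == loci[-1]["motif"][0]:
                tail = ("C" if loci[-1]["motif"][0] != "C" else "G") + tail[1:]
            parts.append(tail)
            seq = "".join(parts)
            # duplicated-flank tail: copy the founder window of flagged loci
            dup_here = [loc for loc in loci if loc["duplicated"]]
            if dup_here:
                founder_contig = _founder_contig(loci, segs)
                tail_parts = [_scrub_repeats(_random_seq(rng, 6000), rng)]  # >window spacer
                for loc in dup_here:
                    w0 = max(loc["founder_start"] - 350, 0)
                    w1 = min(loc["founder_start"] + len(loc["motif"]) * loc["reps"] + 350, len(founder_contig))
                    tail_parts.append(founder_contig[w0:w1])
                    tail_parts.append(_scrub_repeats(_random_seq(rng, 800), rng))
                seq = seq + "".join(tail_parts)
            if cfg.hard_mode:
                decoys = []
                for loc in loci[:: max(len(loci) // 5, 1)]:
                    fc = _founder_contig(loci, segs)
                    w0 = max(loc["founder_start"] - 350, 0)
                    w1 = loc["founder_start"]
                    decoys.append(_mutate_background(fc[w0:w1], 0.05, rng))
                    decoys.append(_scrub_repeats(_random_seq(rng, 500), rng))
                seq = seq + _scrub_repeats(_random_seq(rng, 2000), rng) + "".join(decoys)
            records.append((seq_id, seq))
        genomes.append(GenomeSeq(genome_id=gid, records=records))

    # --- truth table --------------------------------------------------------
    for loc in all_loci:
        k = len(loc["motif"])
        lengths = [
            loc["alleles"][g] * k for g in genome_ids if loc["alleles"][g] is not None
        ]
        n_absent = sum(1 for g in genome_ids if loc["alleles"][g] is None)
        length_poly = len(set(lengths)) >= 2
        if n_absent == 0:
            poly = "length_polymorphic" if length_poly else "monomorphic"
        else:
            poly = "both" if length_poly else "presence_absence"
        row = {
            "locus_index": loc["index"],
            "seq_id": loc["seq_id"],
            "ref_start": loc["founder_start"],
            "ref_end": loc["founder_start"] + k * loc["reps"],
            "motif": loc["motif"],
            "motif_len": k,
            "founder_repeats": loc["reps"],
            "duplicated": loc["duplicated"],
            "expected_unique": not loc["duplicated"],
            "expected_poly_class": poly,
        }
        for g in genome_ids:
            reps = loc["alleles"][g]
            row[f"repeats_{g}"] = ABSENT if reps is None else reps
            row[f"start_{g}"] = (
                -1 if per_genome_starts[g][loc["index"]] is None else per_genome_starts[g][loc["index"]]
            )
        truth_rows.append(row)
    truth = pd.DataFrame(truth_rows).sort_values(["seq_id", "ref_start"]).reset_index(drop=True)

    gff = _synthetic_gff(contig_plans, founder_segments, cfg, rng)
    return SimResult(genomes=genomes, gff=gff, truth=truth)


def _founder_contig(loci, segs) -> str:
    parts = []
    cursor = 0
    for j, loc in enumerate(loci):
        parts.append(segs[j])
        cursor += len(segs[j])
        loc["founder_start"] = cursor
        tract = loc["motif"] * loc["reps"]
        parts.append(tract)
        cursor += len(tract)
    parts.append(segs[-1])
    return "".join(parts)


def _synthetic_gff(contig_plans, founder_segments, cfg: SimConfig, rng) -> list[GFFFeature]:
    """Sparse synthetic gene models over the founder coordinates.

    Two-exon genes (5'UTR / CDS / intron / CDS / 3'UTR) on alternating
    strands, spaced so each keeps a clear 2 kb promoter window.
    """
    features: list[GFFFeature] = []
    gene_n = 0
    for (seq_id, length, loci), segs in zip(contig_plans, founder_segments):
        # make sure founder_start is populated
        _founder_contig(loci, segs)
        n_genes = int(cfg.gene_model_density * length / 1000)
        if n_genes == 0:
            continue
        stride = length // (n_genes + 1)
        for i in range(n_genes):
            gene_n += 1
            gstart0 = 2500 + i * stride  # leave room for the upstream promoter
            glen = 3000
            if gstart0 + glen + 2500 > length:
                break
            strand = "+" if i % 2 == 0 else "-"
            gid = f"gene{gene_n}"
            mid = f"mRNA{gene_n}"
            exon1 = (gstart0, gstart0 + 1200)
            exon2 = (gstart0 + 2000, gstart0 + glen)
            if strand == "+":
                utr5 = (exon1[0], exon1[0] + 200)
                cds1 = (utr5[1], exon1[1])
                cds2 = (exon2[0], exon2[1] - 200)
                utr3 = (cds2[1], exon2[1])
            else:
                utr3 = (exon1[0], exon1[0] + 200)
                cds1 = (utr3[1], exon1[1])
                cds2 = (exon2[0], exon2[1] - 200)
                utr5 = (cds2[1], exon2[1])

            def F(ftype, iv, fid=None, parent=None):
                return GFFFeature(
                    seq_id=seq_id,
                    type=ftype,
                    start=iv[0] + 1,
                    end=iv[1],
                    strand=strand,
                    feature_id=fid,
                    parent=parent,
                )

            features.append(F("gene", (gstart0, gstart0 + glen), fid=gid))
            features.append(F("mRNA", (gstart0, gstart0 + glen), fid=mid, parent=gid))
            features.append(F("exon", exon1, parent=mid))
            features.append(F("exon", exon2, parent=mid))
            features.append(F("five_prime_UTR", utr5, parent=mid))
            features.append(F("CDS", cds1, parent=mid))
            features.append(F("CDS", cds2, parent=mid))
            features.append(F("three_prime_UTR", utr3, parent=mid))
    return features


def write_panel(result: SimResult, out_dir: str | Path) -> None:
    """Write per-genome FASTA, the shared GFF3 and truth.tsv into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for g in result.genomes:
        write_fasta(g, out / f"{g.genome_id}.fa")
    write_gff3(result.gff, out / "annotation.gff3")
    result.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
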