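"""Detection of perfect microsatellite (SSR) tracts and motif classification.

A perfect SSR is an uninterrupted tandem array of a single 1-6 bp motif. The
detector reports every maximal array whose repeat count reaches the per-motif-
length minimum (MISA-style thresholds: 10 copies for mononucleotide motifs, 7
for di-, 6 for tri-, 5 for tetra- and 4 for penta- and hexanucleotide motifs).
A tract whose motif is itself a whole-number repetition of a shorter motif
(e.g. ATAT = (AT)x2) is reported once, under the shortest motif, and two
reported tracts never share a base: overlap conflicts go to the longer tract,
ties to the smaller motif length, then to the leftmost tract. Runs of N
terminate tracts; a repeat is never called across an N.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GenomeSeq, revcomp

DEFAULT_MIN_REPEATS = {1: 10, 2: 7, 3: 6, 4: 5, 5: 4, 6: 4}

#: Table-style repeat-count bins used for repeat-class summaries.
REPEAT_BINS = [
    ("<5", 0, 4),
    ("5-7", 5, 7),
    ("8-10", 8, 10),
    ("11-15", 11, 15),
    ("16-20", 16, 20),
    ("21-25", 21, 25),
    ("26-30", 26, 30),
    ("31-40", 31, 40),
    (">40", 41, 10**9),
]


@dataclass
class DetectionConfig:
    """Minimum repeat counts per motif length (detection thresholds)."""

    min_repeats: dict[int, int] = field(default_factory=lambda: dict(DEFAULT_MIN_REPEATS))
    max_motif_len: int = 6

    def __post_init__(self) -> None:
        if sorted(self.min_repeats) != list(range(1, self.max_motif_len + 1)):
            raise ValueError("min_repeats keys must be exactly 1..max_motif_len")
        if any(v < 2 for v in self.min_repeats.values()):
            raise ValueError("all repeat thresholds must be >= 2")


@dataclass(frozen=True)
class SSRTract:
    """One perfect repeat tract (0-based half-open coordinates)."""

    genome_id: str
    seq_id: str
    start: int
    end: int
    motif: str
    repeat_count: int

    @property
    def motif_len(self) -> int:
        return len(self.motif)

    @property
    def tract_seq(self) -> str:
        return self.motif * self.repeat_count

    @property
    def length(self) -> int:
        return self.end - self.start

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.motif) * self.repeat_count:
            raise ValueError("tract span must equal motif_len * repeat_count")


def _minimal_period(motif: str) -> int:
    """Length of the shortest string whose repetition yields ``motif``."""
    n = len(motif)
    for p in range(1, n):
        if n % p == 0 and motif == motif[:p] * (n // p):
            return p
    return n


def _candidate_tracts(seq: str, k: int, min_rep: int) -> list[tuple[int, int, str, int]]:
    """All maximal perfect k-mer arrays of >= min_rep copies, primitive motifs only.

    Uses the self-match array m[i] = (seq[i] == seq[i+k]): a maximal run of
    True from a to b-1 marks a maximal k-periodic stretch seq[a : b+k), whose
    leading whole motif copies form the tract. Positions involving N never
    match, so repeats are not called across N.
    """
    n = len(seq)
    if n < (min_rep * k):
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    match = arr[:-k] == arr[k:]
    match &= arr[:-k] != ord("N")
    if not match.any():
        return []
    # boundaries of maximal True runs
    padded = np.concatenate(([False], match, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.where(diff == 1)[0]
    ends = np.where(diff == -1)[0]
    out = []
    for a, b in zip(starts, ends):
        span = (b - a) + k  # periodic stretch length incl. trailing partial
        reps = span // k
        if reps < min_rep:
            continue
        motif = seq[a : a + k]
        if _minimal_period(motif) != k:
            continue  # repetition of a shorter motif: reported at that length
        out.append((int(a), int(a) + int(reps) * k, motif, int(reps)))
    return out


def find_ssrs(genome: GenomeSeq, cfg: DetectionConfig | None = None) -> list[SSRTract]:
    """Detect all maximal perfect SSR tracts meeting the repeat thresholds.

    Returns tracts sorted by (seq_id, start). Overlaps between candidate
    tracts of different motif lengths are resolved so that no two reported
    tracts share a base (longer tract wins; ties: smaller motif length, then
    leftmost).
    """
    cfg = cfg or DetectionConfig()
    tracts: list[SSRTract] = []
    for seq_id, seq in genome.records:
        candidates: list[tuple[int, int, str, int]] = []
        for k in range(1, cfg.max_motif_len + 1):
            candidates.extend(_candidate_tracts(seq, k, cfg.min_repeats[k]))
        # resolution priority: longer span, then smaller motif, then leftmost
        candidates.sort(key=lambda c: (-(c[1] - c[0]), len(c[2]), c[0]))
        taken: list[tuple[int, int]] = []
        accepted = []
        for start, end, motif, reps in candidates:
            if any(start < e and s < end for s, e in taken):
                continue
            taken.append((start, end))
            accepted.append((start, end, motif, reps))
        for start, end, motif, reps in sorted(accepted):
            tracts.append(
                SSRTract(
                    genome_id=genome.genome_id,
                    seq_id=seq_id,
                    start=start,
                    end=end,
                    motif=motif,
                    repeat_count=reps,
                )
            )
    tracts.sort(key=lambda t: (t.seq_id, t.start))
    return tracts


def classify_motif(motif: str) -> str:
    """Canonical strand-collapsed class label for a motif.

    A motif and its reverse complement belong to one class, labelled
    ``"X/Y"`` with X the lexicographically smaller of the two (``"AG/CT"``);
    a self-reverse-complementary motif gets a single-name label (``"AT"``).
    Cyclic rotations are NOT collapsed: ``"GA/TC"`` is distinct from
    ``"AG/CT"``, matching the convention of keeping observed repeat phases
    apart in repeat-type tables.
    """
    if not motif or len(motif) > 6 or not set(motif) <= set("ACGT"):
        raise ValueError(f"invalid motif {motif!r}")
    rc = revcomp(motif)
    if rc == motif:
        return motif
    a, b = sorted([motif, rc])
    return f"{a}/{b}"


def canonical_motif_group(motif: str) -> str:
    """Fully canonical motif group: minimal cyclic rotation over both strands.

    Used for cross-genome locus merging, where boundary jitter between genomes
    can shift the observed phase of the same underlying repeat.
    """
    forms = []
    for m in (motif, revcomp(motif)):
        for i in range(len(m)):
            forms.append(m[i:] + m[:i])
    return min(forms)


def _bin_label(reps: int) -> str:
    for label, lo, hi in REPEAT_BINS:
        if lo <= reps <= hi:
            return label
    raise AssertionError("unreachable")


def repeat_class_table(tracts: list[SSRTract]) -> pd.DataFrame:
    """Per-motif-class repeat summary: counts per repeat-count bin, total,
    average repeat number and average repeat length in bp.

    Index: motif class label; columns: one per repeat bin, then "total",
    "avg_repeat_number" and "avg_repeat_length_bp" (= mean repeat count x
    motif length).
    """
    bin_labels = [b[0] for b in REPEAT_BINS]
    rows: dict[str, dict] = {}
    for t in tracts:
        cls = classify_motif(t.motif)
        row = rows.setdefault(
            cls,
            {**{b: 0 for b in bin_labels}, "total": 0, "_rep_sum": 0, "_motif_len": t.motif_len},
        )
        row[_bin_label(t.repeat_count)] += 1
        row["total"] += 1
        row["_rep_sum"] += t.repeat_count
    records = []
    for cls, row in sorted(rows.items()):
        avg_rep = row["_rep_sum"] / row["total"]
        records.append(
            {
                "motif_class": cls,
                **{b: row[b] for b in bin_labels},
                "total": row["total"],
                "avg_repeat_number": round(avg_rep, 2),
                "avg_repeat_length_bp": round(avg_rep * row["_motif_len"], 2),
            }
        )
    df = pd.DataFrame.from_records(records)
    if not df.empty:
        df = df.set_index("motif_class")
    return df


# --- tract table interchange (TSV) -----------------------------------------

TRACT_TSV_COLUMNS = ["genome_id", "seq_id", "start", "end", "motif", "motif_class", "repeats"]


def write_tracts(tracts: list[SSRTract], path) -> None:
    rows = [
        {
            "genome_id": t.genome_id,
            "seq_id": t.seq_id,
            "start": t.start,
            "end": t.end,
            "motif": t.motif,
            "motif_class": classify_motif(t.motif),
            "repeats": t.repeat_count,
        }
        for t in tracts
    ]
    pd.DataFrame(rows, columns=TRACT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tracts(path) -> list[SSRTract]:
    df = pd.read_csv(path, sep="\t", dtype={"genome_id": str, "seq_id": str, "motif": str})
    return [
        SSRTract(
            genome_id=r.genome_id,
            seq_id=r.seq_id,
            start=int(r.start),
            end=int(r.end),
            motif=r.motif,
            repeat_count=int(r.repeats),
        )
        for r in df.itertuples()
    ]
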