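"""Readers/writers for the standard formats the pipeline touches, plus configuration.

All in-memory coordinates are 0-based half-open. Conversion to the 1-based
inclusive convention of GFF3 (and to BED's 0-based half-open, which matches the
internal convention) happens only at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase a DNA string and map every non-ACGTN character to N.

    Returns the normalized sequence and the number of characters mapped to N.
    """
    up = seq.upper()
    if set(up) <= _VALID:
        return up, 0
    out = []
    n_mapped = 0
    for c in up:
        if c in _VALID:
            out.append(c)
        else:
            out.append("N")
            n_mapped += 1
    return "".join(out), n_mapped


class FastaParseError(ValueError):
    pass


@dataclass
class GenomeSeq:
    """One genome: an ordered set of named contig sequences over {A,C,G,T,N}."""

    genome_id: str
    records: list[tuple[str, str]]

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate seq_id in genome {self.genome_id!r}")
        for sid, seq in self.records:
            if not seq:
                raise ValueError(f"empty sequence for {sid!r}")

    @property
    def seq_ids(self) -> list[str]:
        return [sid for sid, _ in self.records]

    def seq(self, seq_id: str) -> str:
        for sid, s in self.records:
            if sid == seq_id:
                return s
        raise KeyError(seq_id)

    def lengths(self) -> dict[str, int]:
        return {sid: len(s) for sid, s in self.records}

    def total_length(self) -> int:
        return sum(len(s) for _, s in self.records)


def read_fasta(path: str | Path, genome_id: str | None = None) -> GenomeSeq:
    """Read a FASTA file into a :class:`GenomeSeq`.

    Headers are truncated at the first whitespace; sequences are uppercased and
    non-ACGTN characters are mapped to N (count logged). The first non-blank
    character of the file must be ``>``.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected '>' header, got {line.strip()[:20]!r}"
                    )
                break
        else:
            raise FastaParseError(f"{path}: empty FASTA file")

    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    total_mapped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id  # SeqIO already truncates at whitespace
        if sid in seen:
            raise FastaParseError(f"{path}: duplicate seq_id {sid!r}")
        seen.add(sid)
        seq, n_mapped = normalize_sequence(str(rec.seq))
        total_mapped += n_mapped
        records.append((sid, seq))
    if total_mapped:
        logger.info("%s: mapped %d non-ACGTN characters to N", path, total_mapped)
    return GenomeSeq(genome_id=genome_id or path.stem, records=records)


def write_fasta(genome: GenomeSeq, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in genome.records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


@dataclass
class GFFFeature:
    """One GFF3 feature with 1-based inclusive coordinates as read."""

    seq_id: str
    type: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    feature_id: str | None
    parent: str | None
    attributes: dict[str, str] = field(default_factory=dict)


class GFFParseError(ValueError):
    pass


def _parse_attributes(col9: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key.strip()] = urllib.parse.unquote(value.strip())
    return attrs


def read_gff3(path: str | Path) -> list[GFFFeature]:
    """Read a GFF3 file into a flat, parent-resolved feature list.

    Coordinates are kept 1-based inclusive as in the file. A feature with
    ``end < start`` is an error; a feature whose ``Parent`` is unknown is
    dropped with a warning.
    """
    path = Path(path)
    features: list[GFFFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GFFParseError(f"{path}: line {lineno}: expected 9 columns, got {len(cols)}")
            seq_id, _source, ftype, start_s, end_s, _score, strand, _phase, col9 = cols
            start, end = int(start_s), int(end_s)
            if end < start:
                raise GFFParseError(f"{path}: line {lineno}: end {end} < start {start}")
            attrs = _parse_attributes(col9)
            features.append(
                GFFFeature(
                    seq_id=seq_id,
                    type=ftype,
                    start=start,
                    end=end,
                    strand=strand,
                    feature_id=attrs.get("ID"),
                    parent=attrs.get("Parent"),
                    attributes=attrs,
                )
            )
    known_ids = {f.feature_id for f in features if f.feature_id}
    kept: list[GFFFeature] = []
    for f in features:
        if f.parent is not None and f.parent not in known_ids:
            logger.warning("%s: dropping %s feature with unknown Parent=%s", path, f.type, f.parent)
            continue
        kept.append(f)
    return kept


def write_gff3(features: Iterable[GFFFeature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            if f.feature_id and "ID" not in attrs:
                attrs["ID"] = f.feature_id
            if f.parent and "Parent" not in attrs:
                attrs["Parent"] = f.parent
            col9 = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                f"{f.seq_id}\t.\t{f.type}\t{f.start}\t{f.end}\t.\t{f.strand}\t.\t{col9}\n"
            )


# ---------------------------------------------------------------------------
# Marker output
# ---------------------------------------------------------------------------

MARKER_TSV_COLUMNS = [
    "marker_id",
    "seq_id",
    "start",
    "end",
    "motif",
    "repeats",
    "fwd_primer",
    "rev_primer",
    "product_size",
    "status",
]


def write_markers(markers: Sequence, path: str | Path, format: str = "tsv") -> None:
    """Write marker candidates as TSV, GFF3 or BED.

    ``markers`` are objects exposing marker_id, seq_id, start, end (0-based
    half-open), motif, repeats, fwd_primer, rev_primer, product_size and
    status attributes (missing primer fields rendered as '.'). The TSV start
    column is the internal 0-based start; GFF3 output is 1-based inclusive and
    BED 0-based half-open.
    """
    path = Path(path)
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("\t".join(MARKER_TSV_COLUMNS) + "\n")
            for m in markers:
                fh.write(
                    "\t".join(
                        str(x)
                        for x in [
                            m.marker_id,
                            m.seq_id,
                            m.start,
                            m.end,
                            m.motif,
                            m.repeats,
                            getattr(m, "fwd_primer", None) or ".",
                            getattr(m, "rev_primer", None) or ".",
                            getattr(m, "product_size", None) or ".",
                            m.status,
                        ]
                    )
                    + "\n"
                )
    elif format == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for m in markers:
                fh.write(
                    f"{m.seq_id}\tssrmine\tmicrosatellite\t{m.start + 1}\t{m.end}\t.\t+\t.\t"
                    f"ID={m.marker_id};motif={m.motif};repeats={m.repeats};status={m.status}\n"
                )
    elif format == "bed":
        with open(path, "w") as fh:
            for m in markers:
                fh.write(f"{m.seq_id}\t{m.start}\t{m.end}\t{m.marker_id}\n")
    else:
        raise ValueError(f"unknown marker format {format!r}")


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Aggregate of every stage configuration, serializable to one YAML file.

    Defaults reproduce the published maize SSR-marker screening parameters:
    MISA-style minimum repeat counts, 300 bp flanks with >90 % identity /
    >85 % coverage uniqueness, the Primer3 constraint box, e-PCR word size 9
    with 1 mismatch / 1 indel, and the 5 kb cross-genome merge window.
    """

    detection: "DetectionConfig" = None  # type: ignore[assignment]
    flank: "FlankConfig" = None  # type: ignore[assignment]
    primer: "PrimerConfig" = None  # type: ignore[assignment]
    epcr: "EPCRConfig" = None  # type: ignore[assignment]
    merge: "MergeConfig" = None  # type: ignore[assignment]
    region: "RegionConfig" = None  # type: ignore[assignment]
    density: "DensityConfig" = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        # late imports: each sub-config lives in its owning module
        from .annotate_stats import DensityConfig, RegionConfig
        from .flank_screen import FlankConfig
        from .insilico_pcr import EPCRConfig
        from .panel_compare import MergeConfig
        from .primer_design import PrimerConfig
        from .ssr_finder import DetectionConfig

        defaults = {
            "detection": DetectionConfig,
            "flank": FlankConfig,
            "primer": PrimerConfig,
            "epcr": EPCRConfig,
            "merge": MergeConfig,
            "region": RegionConfig,
            "density": DensityConfig,
        }
        for name, cls in defaults.items():
            if getattr(self, name) is None:
                setattr(self, name, cls())

    def to_dict(self) -> dict:
        return {
            name: dataclasses.asdict(getattr(self, name))
            for name in ("detection", "flank", "primer", "epcr", "merge", "region", "density")
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .annotate_stats import DensityConfig, RegionConfig
        from .flank_screen import FlankConfig
        from .insilico_pcr import EPCRConfig
        from .panel_compare import MergeConfig
        from .primer_design import PrimerConfig
        from .ssr_finder import DetectionConfig

        classes = {
            "detection": DetectionConfig,
            "flank": FlankConfig,
            "primer": PrimerConfig,
            "epcr": EPCRConfig,
            "merge": MergeConfig,
            "region": RegionConfig,
            "density": DensityConfig,
        }
        kwargs = {}
        for name, klass in classes.items():
            sub = d.get(name, {})
            if name == "detection" and "min_repeats" in sub:
                sub = dict(sub)
                sub["min_repeats"] = {int(k): int(v) for k, v in sub["min_repeats"].items()}
            kwargs[name] = klass(**sub)
        return cls(**kwargs)


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a pipeline configuration; with no path, return all defaults."""
    if path is None:
        return PipelineConfig()
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(d)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
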