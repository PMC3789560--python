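"""End-to-end marker development: detect -> screen flanks -> design primers ->
e-PCR -> merge panel -> classify polymorphism, with the funnel bookkeeping."""

from __future__ import annotations

from dataclasses import dataclass, field

from .flank_screen import FlankedLocus, GenomeIndex, extract_flanks, screen_uniqueness
from .insilico_pcr import SpecificityCall, epcr
from .io_formats import GenomeSeq, PipelineConfig
from .panel_compare import PanelLocus, is_polymorphic, merge_panel
from .primer_design import PrimerPair, design_primers
from .ssr_finder import SSRTract, find_ssrs


@dataclass
class MarkerCandidate:
    """One SSR tract with its screening state, for marker-table export."""

    tract: SSRTract
    status: str  # detected | unique_flanks | primer_designed | epcr_unique | polymorphic
    primers: PrimerPair | None = None

    @property
    def marker_id(self) -> str:
        return f"{self.tract.seq_id}:{self.tract.start}:{self.tract.motif}"

    # flat accessors used by io_formats.write_markers
    @property
    def seq_id(self):
        return self.tract.seq_id

    @property
    def start(self):
        return self.tract.start

    @property
    def end(self):
        return self.tract.end

    @property
    def motif(self):
        return self.tract.motif

    @property
    def repeats(self):
        return self.tract.repeat_count

    @property
    def fwd_primer(self):
        return self.primers.fwd_seq if self.primers else None

    @property
    def rev_primer(self):
        return self.primers.rev_seq if self.primers else None

    @property
    def product_size(self):
        return self.primers.product_len if self.primers else None


@dataclass
class GenomeRun:
    """Per-genome stage outputs of the marker funnel."""

    genome_id: str
    tracts: list[SSRTract]
    flanked: list[FlankedLocus]
    unique: list[FlankedLocus]
    primers: dict[str, PrimerPair]
    epcr_calls: dict[str, SpecificityCall]
    epcr_unique: list[FlankedLocus]


@dataclass
class PanelRun:
    per_genome: dict[str, GenomeRun]
    loci: list[PanelLocus] = field(default_factory=list)

    @property
    def polymorphic(self) -> list[PanelLocus]:
        return [l for l in self.loci if is_polymorphic(l)]


def run_genome(genome: GenomeSeq, cfg: PipelineConfig | None = None) -> GenomeRun:
    """Run detection through e-PCR specificity on a single genome."""
    cfg = cfg or PipelineConfig()
    tracts = find_ssrs(genome, cfg.detection)
    flanked = extract_flanks(tracts, genome, cfg.flank)
    index = GenomeIndex(genome, cfg.flank.seed_len)
    screened = screen_uniqueness(flanked, genome, cfg.flank, index=index)
    unique = [l for l in screened if l.unique]
    primers: dict[str, PrimerPair] = {}
    epcr_calls: dict[str, SpecificityCall] = {}
    epcr_unique: list[FlankedLocus] = []
    for locus in unique:
        pair = design_primers(locus, cfg.primer)
        if pair is None:
            continue
        primers[locus.locus_id] = pair
        call = epcr(pair, genome, cfg.epcr, expected_size=pair.product_len)
        epcr_calls[locus.locus_id] = call
        if call.status == "unique":
            epcr_unique.append(locus)
    return GenomeRun(
        genome_id=genome.genome_id,
        tracts=tracts,
        flanked=flanked,
        unique=unique,
        primers=primers,
        epcr_calls=epcr_calls,
        epcr_unique=epcr_unique,
    )


def run_panel(
    genomes: list[GenomeSeq],
    cfg: PipelineConfig | None = None,
    reference_id: str | None = None,
    full_screen_all: bool = False,
) -> PanelRun:
    """Run the funnel on a reference genome and detection on the rest, then
    merge tracts across the panel into polymorphism-classified loci.

    The flank/primer/e-PCR stages operate on the reference (first genome by
    default); set ``full_screen_all`` to run them on every genome.
    """
    cfg = cfg or PipelineConfig()
    reference_id = reference_id or genomes[0].genome_id
    per_genome: dict[str, GenomeRun] = {}
    tract_sets: dict[str, list[SSRTract]] = {}
    for g in genomes:
        if full_screen_all or g.genome_id == reference_id:
            run = run_genome(g, cfg)
            per_genome[g.genome_id] = run
            tract_sets[g.genome_id] = run.tracts
        else:
            tract_sets[g.genome_id] = find_ssrs(g, cfg.detection)
    loci = merge_panel(tract_sets, cfg.merge)
    return PanelRun(per_genome=per_genome, loci=loci)
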