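"""End-to-end genome screen for readthrough-derived peroxisomal isoforms.

The screen walks every well-formed protein-coding gene, classifies its stop
codon context, calls the in-frame extension past the annotated stop, scans
the extension for a terminal PTS1 and the regular ORF terminus for an in-ORF
PTS1, and assigns one mechanism class per gene. All genes are reported — not
just the TGA-CT hits — because the conservation stage needs the
non-readthrough mechanisms of the same loci; the mechanism column is the
filter.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from .context_model import ContextCall, classify_context
from .extension_caller import ReadthroughExtension, call_extension, translate
from .pts_scanner import (
    Pts1Hit,
    Pts2Hit,
    scan_extension_pts1,
    scan_orf_terminal_pts1,
    scan_pts2,
)
from .sequence_io import (
    GeneModel,
    GeneRecord,
    GenomeMap,
    build_gene_records,
    read_gene_models,
    read_genome,
    write_candidates,
)

log = logging.getLogger("rtscreen")

MECHANISM_READTHROUGH = "readthrough_PTS1"
MECHANISM_READTHROUGH_NONCORE = "readthrough_PTS1_noncore_context"
MECHANISM_IN_ORF = "in_ORF_PTS1"
MECHANISM_PTS2 = "PTS2"
MECHANISM_NONE = "none"

#: priority when several targeting signals coexist
MECHANISM_PRIORITY = (
    MECHANISM_READTHROUGH,
    MECHANISM_READTHROUGH_NONCORE,
    MECHANISM_IN_ORF,
    MECHANISM_PTS2,
    MECHANISM_NONE,
)


@dataclass
class ScreenConfig:
    """Screen parameters.

    ``context_mode='tga-ct'`` (the default) admits only the core TGA CT
    readthrough context; ``'any'`` additionally reports PTS1-bearing
    extensions behind non-core contexts as low-confidence
    ``readthrough_PTS1_noncore_context`` candidates. ``include_pts2`` turns
    on the approximate PTS2 consensus scan.
    """

    flank_len: int = 600
    max_ext_nt: int = 600
    context_mode: str = "tga-ct"  # 'tga-ct' | 'any'
    include_pts2: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.flank_len <= 0 or self.max_ext_nt <= 0:
            raise ValueError("flank_len and max_ext_nt must be positive")
        if self.context_mode not in ("tga-ct", "any"):
            raise ValueError(f"unknown context_mode {self.context_mode!r}")
        if self.flank_len < self.max_ext_nt:
            log.warning(
                "flank_len (%d) < max_ext_nt (%d): extensions are limited by the flank",
                self.flank_len,
                self.max_ext_nt,
            )


@dataclass
class CandidateReport:
    """Per-gene screen verdict."""

    gene_id: str
    contig: str
    strand: str
    start: int
    context: ContextCall
    context_plus1_4: str
    extension: ReadthroughExtension
    pts1: Pts1Hit | None
    orf_terminal_pts1: Pts1Hit | None
    pts2: Pts2Hit | None
    mechanism_class: str
    flank_source: str


def classify_mechanism(
    context: ContextCall,
    pts1: Pts1Hit | None,
    orf_terminal: Pts1Hit | None,
    pts2: Pts2Hit | None,
    config: ScreenConfig,
) -> str:
    """Assign the mechanism class, highest priority signal first:
    readthrough PTS1 > in-ORF PTS1 > PTS2 (if enabled) > none."""
    if pts1 is not None and context.core_pass:
        return MECHANISM_READTHROUGH
    if pts1 is not None and config.context_mode == "any":
        return MECHANISM_READTHROUGH_NONCORE
    if orf_terminal is not None:
        return MECHANISM_IN_ORF
    if config.include_pts2 and pts2 is not None:
        return MECHANISM_PTS2
    return MECHANISM_NONE


def classify_record(record: GeneRecord, config: ScreenConfig) -> CandidateReport:
    """Run context call, extension call and motif scans on one gene."""
    context = classify_context(record.stop_codon, record.flank_nt)
    extension = call_extension(record, config.max_ext_nt)
    pts1 = scan_extension_pts1(extension)
    protein = translate(record.cds_nt[:-3])
    orf_terminal = scan_orf_terminal_pts1(protein)
    pts2 = scan_pts2(protein) if config.include_pts2 else None
    mechanism = classify_mechanism(context, pts1, orf_terminal, pts2, config)
    return CandidateReport(
        gene_id=record.gene_id,
        contig=record.contig,
        strand=record.strand,
        start=record.start,
        context=context,
        context_plus1_4=record.flank_nt[:4],
        extension=extension,
        pts1=pts1,
        orf_terminal_pts1=orf_terminal,
        pts2=pts2,
        mechanism_class=mechanism,
        flank_source=record.flank_source,
    )


def screen_genome(
    genome: GenomeMap,
    models: list[GeneModel],
    config: ScreenConfig | None = None,
    skipped: list[tuple[str, str]] | None = None,
) -> list[CandidateReport]:
    """Screen every gene of a genome; deterministic for fixed inputs.

    Genes failing the core-context filter are still reported (with mechanism
    in_ORF_PTS1 / PTS2 / none) so that conservation analysis can see the
    non-readthrough mechanisms at the same loci.
    """
    config = config or ScreenConfig()
    if skipped is None:
        skipped = []
    records = build_gene_records(genome, models, config.flank_len, skipped=skipped)
    if not records:
        reasons = Counter(reason for _, reason in skipped)
        raise RuntimeError(f"no well-formed genes to screen (skipped: {dict(reasons)})")
    return [classify_record(r, config) for r in records]


def run_summary(
    reports: list[CandidateReport], skipped: list[tuple[str, str]] | None = None
) -> dict:
    """Machine-readable run summary: counts scanned/skipped and per-mechanism
    tallies, in a fixed key order."""
    mech = Counter(r.mechanism_class for r in reports)
    skip = Counter(reason for _, reason in (skipped or []))
    return {
        "n_genes_scanned": len(reports),
        "n_genes_skipped": sum(skip.values()),
        "skip_reasons": dict(sorted(skip.items())),
        "mechanism_counts": {m: mech.get(m, 0) for m in MECHANISM_PRIORITY},
        "n_core_context": sum(1 for r in reports if r.context.core_pass),
    }


def run_screen(
    genome_path: str | Path,
    gff_path: str | Path,
    out_path: str | Path,
    config: ScreenConfig | None = None,
) -> dict:
    """File-to-file screen: FASTA + GFF3 in, candidates TSV plus a JSON run
    summary (``<out>.summary.json``) out. Returns the summary."""
    config = config or ScreenConfig()
    genome = read_genome(genome_path)
    models = read_gene_models(gff_path)
    skipped: list[tuple[str, str]] = []
    reports = screen_genome(genome, models, config, skipped=skipped)
    write_candidates(reports, out_path)
    summary = run_summary(reports, skipped)
    summary_path = Path(str(out_path) + ".summary.json")
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=False) + "\n")
    log.info("screened %d genes -> %s", len(reports), out_path)
    return summary
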