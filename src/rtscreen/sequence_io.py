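"""Genome FASTA / GFF3 input and tabular report output.

Assembles strand-resolved gene records: the coding sequence in reading
orientation (annotated stop codon included) plus the downstream 3' flank,
which is either the spliced 3' UTR (when annotated) or raw genomic sequence.
GFF3 coordinates are 1-based inclusive on disk and converted exactly once to
0-based half-open intervals here; everything downstream works in the internal
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger("rtscreen")

STOP_CODONS = ("TAA", "TAG", "TGA")

#: fixed column order of the candidate report TSV
CANDIDATE_COLUMNS = [
    "gene_id",
    "contig",
    "strand",
    "stop_codon",
    "context_plus1_4",
    "context_core_pass",
    "plus3_A",
    "plus4_G",
    "ext_status",
    "ext_len_aa",
    "ext_peptide",
    "pts1_hit",
    "pts1_tripeptide",
    "orf_terminal_pts1",
    "mechanism_class",
    "flank_source",
]

_VALID = set("ACGTN")


@dataclass(frozen=True)
class GenomeMap:
    """Contig id -> uppercase DNA sequence over the alphabet {A,C,G,T,N}."""

    contigs: Mapping[str, str]

    def __post_init__(self):
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} has an empty sequence")

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass
class GeneModel:
    """One gene's chosen transcript, in 0-based half-open contig coordinates.

    ``cds_segments`` are non-overlapping and sorted in transcription order
    (ascending starts on '+', descending on '-'); their total length must be
    a multiple of 3 for the gene to enter the screen.
    """

    gene_id: str
    contig: str
    strand: str  # '+' or '-'
    cds_segments: list[tuple[int, int]]
    utr3_segments: list[tuple[int, int]] = field(default_factory=list)
    transcript_id: str | None = None

    @property
    def start(self) -> int:
        """Leftmost CDS coordinate, used for deterministic report ordering."""
        return min(s for s, _ in self.cds_segments)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_segments)


@dataclass
class GeneRecord:
    """Strand-resolved coding sequence plus downstream flank, both 5'->3'
    in the coding sense. ``cds_nt`` ends with the annotated stop codon."""

    gene_id: str
    contig: str
    strand: str
    start: int
    cds_nt: str
    flank_nt: str
    flank_source: str  # 'spliced_utr' or 'genomic'
    flank_truncated: bool = False

    @property
    def stop_codon(self) -> str:
        return self.cds_nt[-3:]


def _normalize(seq: str, contig: str) -> str:
    """Uppercase, RNA->DNA, and collapse non-ACGT letters to N."""
    s = seq.upper().replace("U", "T")
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        log.warning("contig %s: replacing non-ACGTN characters %s with N", contig, bad)
        s = "".join(c if c in _VALID else "N" for c in s)
    return s


def read_genome(path: str | Path) -> GenomeMap:
    """Load a (multi-)FASTA file into a :class:`GenomeMap`.

    Sequences are uppercased and U is converted to T. Duplicate contig ids
    and empty files are hard errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        contigs[rec.id] = _normalize(str(rec.seq), rec.id)
    if not contigs:
        raise ValueError(f"no FASTA records found in {path}")
    return GenomeMap(contigs)


def _segments(features) -> list[tuple[int, int]]:
    # gffutils features are 1-based inclusive; convert here, once.
    return [(f.start - 1, f.end) for f in features]


def read_gene_models(gff_path: str | Path) -> list[GeneModel]:
    """Parse a GFF3 file into one :class:`GeneModel` per gene.

    When a gene has several mRNAs, the transcript with the longest total CDS
    is kept; ties break on the lexicographically smallest transcript id.
    CDS features parented directly by a gene (no mRNA level) are accepted.
    """
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts = list(db.children(gene, featuretype="mRNA", level=1))
        transcripts += list(db.children(gene, featuretype="transcript", level=1))
        best: tuple[int, str, list, list] | None = None
        candidates = transcripts if transcripts else [gene]
        for t in candidates:
            cds = list(db.children(t, featuretype="CDS", order_by="start"))
            if not cds:
                continue
            utr3 = list(db.children(t, featuretype="three_prime_UTR", order_by="start"))
            total = sum(f.end - f.start + 1 for f in cds)
            key = (-total, t.id)
            if best is None or key < (-best[0], best[1]):
                best = (total, t.id, cds, utr3)
        if best is None:
            log.warning("gene %s has no CDS features; skipped", gene.id)
            continue
        _, tid, cds, utr3 = best
        cds_segs = _segments(cds)
        utr3_segs = _segments(utr3)
        if gene.strand == "-":
            cds_segs = cds_segs[::-1]
            utr3_segs = utr3_segs[::-1]
        models.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                cds_segments=cds_segs,
                utr3_segments=utr3_segs,
                transcript_id=tid if transcripts else None,
            )
        )
    return models


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _spliced(contig_seq: str, segments: Iterable[tuple[int, int]], strand: str) -> str:
    parts = []
    for s, e in segments:
        piece = contig_seq[s:e]
        parts.append(_revcomp(piece) if strand == "-" else piece)
    return "".join(parts)


def build_gene_records(
    genome: GenomeMap,
    models: list[GeneModel],
    flank_len: int = 600,
    skipped: list[tuple[str, str]] | None = None,
) -> list[GeneRecord]:
    """Assemble :class:`GeneRecord` objects, reading-orientation resolved.

    Minus-strand genes are reverse-complemented so ``cds_nt`` and ``flank_nt``
    both read 5'->3' in the coding sense. The flank is the spliced 3' UTR when
    annotated (``flank_source='spliced_utr'``), else ``flank_len`` nt of
    genomic sequence downstream of the stop codon, truncated at the contig
    edge with the record flagged. Genes whose CDS length is not a multiple of
    3 or that lack a terminal stop codon are skipped with a warning (optionally
    collected into ``skipped`` as ``(gene_id, reason)``).
    """
    if flank_len < 3:
        raise ValueError("flank_len must be >= 3")
    records: list[GeneRecord] = []
    for m in models:
        if m.contig not in genome:
            raise KeyError(f"gene {m.gene_id}: contig {m.contig!r} not in genome")
        contig_seq = genome[m.contig]
        for s, e in m.cds_segments:
            if s < 0 or e > len(contig_seq) or s >= e:
                raise ValueError(f"gene {m.gene_id}: segment ({s},{e}) outside contig")
        cds_nt = _spliced(contig_seq, m.cds_segments, m.strand)
        reason = None
        if len(cds_nt) % 3 != 0:
            reason = "cds_not_multiple_of_3"
        elif cds_nt[-3:] not in STOP_CODONS:
            reason = "no_terminal_stop"
        if reason:
            log.warning("gene %s skipped: %s", m.gene_id, reason)
            if skipped is not None:
                skipped.append((m.gene_id, reason))
            continue

        truncated = False
        if m.utr3_segments:
            flank_nt = _spliced(contig_seq, m.utr3_segments, m.strand)
            flank_source = "spliced_utr"
        else:
            flank_source = "genomic"
            if m.strand == "+":
                end3 = max(e for _, e in m.cds_segments)
                flank_nt = contig_seq[end3 : end3 + flank_len]
            else:
                start3 = min(s for s, _ in m.cds_segments)
                flank_nt = _revcomp(contig_seq[max(0, start3 - flank_len) : start3])
            truncated = len(flank_nt) < flank_len
        records.append(
            GeneRecord(
                gene_id=m.gene_id,
                contig=m.contig,
                strand=m.strand,
                start=m.start,
                cds_nt=cds_nt,
                flank_nt=flank_nt,
                flank_source=flank_source,
                flank_truncated=truncated,
            )
        )
    return records


def write_candidates(reports, path: str | Path) -> None:
    """Write candidate reports as a UTF-8 TSV with a fixed column set.

    Rows are sorted by (contig, start, gene_id) so re-running on identical
    input produces a byte-identical file.
    """
    rows = []
    for r in reports:
        ext = r.extension
        ctx = r.context
        rows.append(
            {
                "gene_id": r.gene_id,
                "contig": r.contig,
                "strand": r.strand,
                "_start": r.start,
                "stop_codon": ctx.stop_codon,
                "context_plus1_4": r.context_plus1_4,
                "context_core_pass": ctx.core_pass,
                "plus3_A": ctx.plus3_A,
                "plus4_G": ctx.plus4_G,
                "ext_status": ext.status,
                "ext_len_aa": len(ext.ext_aa),
                "ext_peptide": ext.ext_aa,
                "pts1_hit": r.pts1 is not None,
                "pts1_tripeptide": r.pts1.tripeptide if r.pts1 else "",
                "orf_terminal_pts1": r.orf_terminal_pts1.tripeptide if r.orf_terminal_pts1 else "",
                "mechanism_class": r.mechanism_class,
                "flank_source": r.flank_source,
            }
        )
    df = pd.DataFrame(rows, columns=["_start"] + CANDIDATE_COLUMNS if rows else CANDIDATE_COLUMNS)
    if rows:
        df = df.sort_values(["contig", "_start", "gene_id"], kind="mergesort")
        df = df.drop(columns="_start")
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
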