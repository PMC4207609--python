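"""Synthetic genomes with planted readthrough-PTS1 structure.

Generates FASTA + GFF3 + a truth table so every pipeline stage can be tested
end to end without downloading a real genome. Planted gene classes:

* ``readthrough_PTS1`` — stop TGA, +1..+3 = CTA (the core readthrough
  element with the +3 A enhancer), then an in-frame extension whose last
  tripeptide is drawn uniformly from the PTS1 set, then a second stop.
* ``context_only`` — TGA CT context but a PTS1-free extension (decoy).
* ``pts1_wrong_stop`` — a PTS1-ending extension behind CTA, but the stop is
  TAA/TAG, not TGA (decoy; a candidate only under ``context_mode='any'``).
* ``in_orf_pts1`` — the regular ORF already ends in a PTS1 tripeptide; no
  readthrough needed ("no readthrough" mechanism).
* ``background`` — everything else.

Background cleanliness is enforced by rejection sampling, not post-hoc
filtering: a background 3' flank is resampled until its first in-frame
extension terminates inside the gene's own intergenic spacer, does not end
in a PTS1 tripeptide, and does not sit behind a TGA CT context; background
ORF termini are likewise resampled out of the PTS1 set. Roughly 0.46% of
random tripeptides (37/8000) are PTS1 and 1/192 of random stop contexts are
TGA CT, so without rejection the truth table would be contaminated
stochastically. By construction the screen's readthrough_PTS1 call set
equals the planted truth set exactly. The same seed yields byte-identical
output files.

Codon usage is uniform over sense codons; the screen is codon-usage
agnostic, so no species-specific usage or UTR length distribution is
emulated.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .extension_caller import GENETIC_CODE, STOP_CODONS, translate
from .pts_scanner import pts1_tripeptide_set, pts1_tripeptides
from .sequence_io import GeneModel, GenomeMap

SENSE_CODONS = sorted(c for c, aa in GENETIC_CODE.items() if aa != "*")

_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon in SENSE_CODONS:
    _AA_TO_CODONS.setdefault(GENETIC_CODE[_codon], []).append(_codon)

CLASS_READTHROUGH = "readthrough_PTS1"
CLASS_CONTEXT_ONLY = "context_only"
CLASS_WRONG_STOP = "pts1_wrong_stop"
CLASS_IN_ORF = "in_orf_pts1"
CLASS_BACKGROUND = "background"

_GENES_PER_CONTIG = 100


@dataclass
class SimConfig:
    """Simulation parameters; defaults give a 200-gene genome with 10 genes
    per planted class. Ranges are inclusive; lengths are codons for CDS and
    extensions, nucleotides for intergenic spacers."""

    n_genes: int = 200
    n_planted_readthrough_pts1: int = 10
    n_decoy_context_only: int = 10
    n_decoy_pts1_wrong_stop: int = 10
    n_decoy_in_orf_pts1: int = 10
    cds_len_range: tuple[int, int] = (100, 300)
    ext_len_range: tuple[int, int] = (5, 30)
    intergenic_len_range: tuple[int, int] = (80, 200)
    minus_strand_fraction: float = 0.5
    seed: int = 42

    def validate(self) -> None:
        planted = (
            self.n_planted_readthrough_pts1
            + self.n_decoy_context_only
            + self.n_decoy_pts1_wrong_stop
            + self.n_decoy_in_orf_pts1
        )
        if planted > self.n_genes:
            raise ValueError("planted + decoy genes exceed n_genes")
        for name in ("cds_len_range", "ext_len_range", "intergenic_len_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.cds_len_range[0] < 10:
            raise ValueError("cds_len_range minimum must be >= 10 codons")
        needs_ext = (
            self.n_planted_readthrough_pts1
            + self.n_decoy_context_only
            + self.n_decoy_pts1_wrong_stop
        )
        if needs_ext > 0 and self.ext_len_range[1] < 4:
            raise ValueError(
                "ext_len_range max must be >= 4 codons to fit the CT(A) context "
                "plus a terminal tripeptide"
            )
        if needs_ext > 0 and self.ext_len_range[0] < 4:
            raise ValueError("ext_len_range minimum must be >= 4 codons")
        if not 0.0 <= self.minus_strand_fraction <= 1.0:
            raise ValueError("minus_strand_fraction must be in [0, 1]")


@dataclass
class SimResult:
    genome: GenomeMap
    models: list[GeneModel]
    truth: pd.DataFrame  # gene_id, planted_class, planted_tripeptide

    def write(self, out_prefix: str | Path) -> tuple[Path, Path, Path]:
        """Write ``<prefix>.fa``, ``<prefix>.gff3`` and ``<prefix>.truth.tsv``."""
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        fasta = prefix.with_suffix(prefix.suffix + ".fa")
        gff = prefix.with_suffix(prefix.suffix + ".gff3")
        truth = prefix.with_suffix(prefix.suffix + ".truth.tsv")
        with open(fasta, "w") as fh:
            for cid in self.genome.contigs:
                fh.write(f">{cid}\n")
                seq = self.genome[cid]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            for m in self.models:
                s, e = m.cds_segments[0]
                gid, tid = m.gene_id, f"{m.gene_id}.t1"
                line = f"{m.contig}\trtscreen_sim\t{{ft}}\t{s + 1}\t{e}\t.\t{m.strand}\t{{ph}}\t{{attr}}\n"
                fh.write(line.format(ft="gene", ph=".", attr=f"ID={gid}"))
                fh.write(line.format(ft="mRNA", ph=".", attr=f"ID={tid};Parent={gid}"))
                fh.write(line.format(ft="CDS", ph="0", attr=f"ID={tid}.cds;Parent={tid}"))
        self.truth.to_csv(truth, sep="\t", index=False, lineterminator="\n")
        return fasta, gff, truth


def _random_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def _random_sense_codons(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(SENSE_CODONS) for _ in range(n))


def _encode(rng: random.Random, peptide: str) -> str:
    return "".join(rng.choice(_AA_TO_CODONS[aa]) for aa in peptide)


def _orf(rng: random.Random, config: SimConfig, terminal_tripeptide: str | None) -> str:
    """ATG + random sense codons, optionally forcing (or forbidding) a PTS1
    tripeptide at the protein's C-terminus. Excludes the stop codon."""
    pts1 = pts1_tripeptide_set()
    n_internal = rng.randint(*config.cds_len_range)
    internal = _random_sense_codons(rng, n_internal)
    if terminal_tripeptide is not None:
        internal = internal[:-9] + _encode(rng, terminal_tripeptide)
    else:
        while translate(internal[-9:]) in pts1:
            internal = internal[:-9] + _random_sense_codons(rng, 3)
    return "ATG" + internal


def _first_inframe_extension(spacer: str) -> tuple[str, str | None]:
    """(extension nt, terminal stop or None) of a codon walk along ``spacer``."""
    for i in range(0, len(spacer) // 3 * 3, 3):
        codon = spacer[i : i + 3]
        if codon in STOP_CODONS:
            return spacer[:i], codon
    return spacer, None


def _safe_spacer(rng: random.Random, config: SimConfig, stop_codon: str) -> str:
    """Random intergenic spacer guaranteed to contribute no candidate signal:
    its first in-frame extension closes inside the spacer, does not end in a
    PTS1 tripeptide, and the +1/+2 context is not CT behind a TGA stop."""
    pts1 = pts1_tripeptide_set()
    while True:
        spacer = _random_nt(rng, rng.randint(*config.intergenic_len_range))
        if stop_codon == "TGA" and spacer[:2] == "CT":
            continue
        ext_nt, terminal = _first_inframe_extension(spacer)
        if terminal is None:
            continue
        if len(ext_nt) >= 9 and translate(ext_nt)[-3:] in pts1:
            continue
        return spacer


def _planted_extension(
    rng: random.Random,
    config: SimConfig,
    first_codon: str,
    tripeptide: str | None,
) -> tuple[str, str]:
    """(extension nt, terminal stop). ``tripeptide=None`` means a PTS1-free
    terminal tripeptide (the context-only decoy)."""
    pts1 = pts1_tripeptide_set()
    n_codons = rng.randint(*config.ext_len_range)
    middle = _random_sense_codons(rng, n_codons - 4)
    if tripeptide is not None:
        tail = _encode(rng, tripeptide)
    else:
        tail = _random_sense_codons(rng, 3)
        while translate(tail) in pts1:
            tail = _random_sense_codons(rng, 3)
    return first_codon + middle + tail, rng.choice(STOP_CODONS)


def simulate_genome(config: SimConfig | None = None) -> SimResult:
    """Generate a genome, annotation and truth table per ``config``.

    Deterministic for a fixed seed. Gene units (CDS + downstream region) are
    laid out sequentially, at most 100 genes per contig; minus-strand genes
    are reverse-complemented in place, so their 3' flank lies to the left of
    the CDS in contig coordinates.
    """
    config = config or SimConfig()
    config.validate()
    rng = random.Random(config.seed)
    pts1_list = pts1_tripeptides()

    classes = (
        [CLASS_READTHROUGH] * config.n_planted_readthrough_pts1
        + [CLASS_CONTEXT_ONLY] * config.n_decoy_context_only
        + [CLASS_WRONG_STOP] * config.n_decoy_pts1_wrong_stop
        + [CLASS_IN_ORF] * config.n_decoy_in_orf_pts1
    )
    classes += [CLASS_BACKGROUND] * (config.n_genes - len(classes))
    rng.shuffle(classes)

    contigs: dict[str, str] = {}
    models: list[GeneModel] = []
    truth_rows = []

    parts: list[str] = []
    offset = 0
    contig_idx = 1

    def _contig_id() -> str:
        return f"ctg{contig_idx:02d}"

    for i, cls in enumerate(classes):
        gene_id = f"g{i + 1:04d}"
        tripeptide = None
        if cls == CLASS_READTHROUGH:
            orf = _orf(rng, config, None)
            stop = "TGA"
            tripeptide = rng.choice(pts1_list)
            ext, terminal = _planted_extension(rng, config, "CTA", tripeptide)
            downstream = ext + terminal + _random_nt(rng, rng.randint(*config.intergenic_len_range))
        elif cls == CLASS_CONTEXT_ONLY:
            orf = _orf(rng, config, None)
            stop = "TGA"
            ext, terminal = _planted_extension(rng, config, "CT" + rng.choice("ACGT"), None)
            downstream = ext + terminal + _random_nt(rng, rng.randint(*config.intergenic_len_range))
        elif cls == CLASS_WRONG_STOP:
            orf = _orf(rng, config, None)
            stop = rng.choice(("TAA", "TAG"))
            tripeptide = rng.choice(pts1_list)
            ext, terminal = _planted_extension(rng, config, "CTA", tripeptide)
            downstream = ext + terminal + _random_nt(rng, rng.randint(*config.intergenic_len_range))
        elif cls == CLASS_IN_ORF:
            tripeptide = rng.choice(pts1_list)
            orf = _orf(rng, config, tripeptide)
            stop = rng.choice(STOP_CODONS)
            downstream = _safe_spacer(rng, config, stop)
        else:
            orf = _orf(rng, config, None)
            stop = rng.choice(STOP_CODONS)
            downstream = _safe_spacer(rng, config, stop)

        cds = orf + stop
        unit = cds + downstream
        minus = rng.random() < config.minus_strand_fraction
        if minus:
            placed = _revcomp(unit)
            cds_start = offset + len(downstream)
            cds_end = offset + len(unit)
            strand = "-"
        else:
            placed = unit
            cds_start = offset
            cds_end = offset + len(cds)
            strand = "+"
        parts.append(placed)
        offset += len(unit)
        models.append(
            GeneModel(
                gene_id=gene_id,
                contig=_contig_id(),
                strand=strand,
                cds_segments=[(cds_start, cds_end)],
            )
        )
        truth_rows.append(
            {
                "gene_id": gene_id,
                "planted_class": cls,
                "planted_tripeptide": tripeptide or "",
            }
        )

        if (i + 1) % _GENES_PER_CONTIG == 0 or i + 1 == len(classes):
            contigs[_contig_id()] = "".join(parts)
            parts = []
            offset = 0
            contig_idx += 1

    return SimResult(
        genome=GenomeMap(contigs),
        models=models,
        truth=pd.DataFrame(truth_rows, columns=["gene_id", "planted_class", "planted_tripeptide"]),
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
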