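"""Cross-species conservation of the peroxisomal targeting mechanism.

Ortholog groups arrive precomputed as a TSV (one row per species per gene:
group_id, species, gene_id, protein_aa, stop_codon, flank_nt); orthology
inference itself is out of scope. Each entry is classified with exactly the
same machinery as the genome screen — context call on the stop codon and
flank, extension call, PTS1 scans — and a group is summarised as a
presence/absence mechanism matrix across its species, the tabular analogue
of a per-species conservation colouring. "Conservation" here means
presence/absence tabulation, not phylogenetic reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .context_model import STOP_CODONS, classify_context
from .extension_caller import call_extension_nt
from .pts_scanner import scan_extension_pts1, scan_orf_terminal_pts1, scan_pts2
from .screen_pipeline import (
    MECHANISM_IN_ORF,
    MECHANISM_NONE,
    MECHANISM_PRIORITY,
    MECHANISM_PTS2,
    MECHANISM_READTHROUGH,
    MECHANISM_READTHROUGH_NONCORE,
    ScreenConfig,
    classify_mechanism,
)

GROUP_COLUMNS = ["group_id", "species", "gene_id", "protein_aa", "stop_codon", "flank_nt"]

_RANK = {m: i for i, m in enumerate(MECHANISM_PRIORITY)}


@dataclass(frozen=True)
class OrthologEntry:
    """One species' representative of an ortholog group: the regular ORF
    translation (no stop), its stop codon, and the 3' flank nucleotides."""

    group_id: str
    species: str
    gene_id: str
    protein_aa: str
    stop_codon: str
    flank_nt: str

    def __post_init__(self):
        if self.stop_codon not in STOP_CODONS:
            raise ValueError(
                f"{self.group_id}/{self.species}: stop_codon {self.stop_codon!r} is not a stop"
            )


@dataclass
class ConservationSummary:
    group_id: str
    per_species: dict[str, str]  # species -> mechanism_class
    n_readthrough_PTS1: int
    n_readthrough_PTS1_noncore: int
    n_in_ORF_PTS1: int
    n_PTS2: int
    n_none: int
    conserved_core_context: bool


def classify_entry(entry: OrthologEntry, config: ScreenConfig | None = None) -> str:
    """Mechanism class of one ortholog entry, computed exactly as in the
    genome screen. An empty flank simply yields no extension, so the
    mechanism falls back to the ORF terminus (and PTS2 if enabled)."""
    config = config or ScreenConfig()
    context = classify_context(entry.stop_codon, entry.flank_nt)
    extension = call_extension_nt(entry.flank_nt, config.max_ext_nt)
    pts1 = scan_extension_pts1(extension)
    orf_terminal = scan_orf_terminal_pts1(entry.protein_aa)
    pts2 = scan_pts2(entry.protein_aa) if config.include_pts2 else None
    return classify_mechanism(context, pts1, orf_terminal, pts2, config)


def summarize_group(
    entries: list[OrthologEntry], config: ScreenConfig | None = None
) -> ConservationSummary:
    """Per-species mechanism table plus aggregate counts for one group.

    A species present more than once keeps its best-priority mechanism.
    ``conserved_core_context`` is true iff every readthrough-positive species
    carries the TGA CT core context.
    """
    if not entries:
        raise ValueError("empty ortholog group")
    group_ids = {e.group_id for e in entries}
    if len(group_ids) > 1:
        raise ValueError(f"mixed group ids in one group: {sorted(group_ids)}")
    config = config or ScreenConfig()

    per_species: dict[str, str] = {}
    core_by_species: dict[str, bool] = {}
    for e in entries:
        mech = classify_entry(e, config)
        prev = per_species.get(e.species)
        if prev is None or _RANK[mech] < _RANK[prev]:
            per_species[e.species] = mech
            ctx = classify_context(e.stop_codon, e.flank_nt)
            core_by_species[e.species] = ctx.core_pass

    readthrough = {MECHANISM_READTHROUGH, MECHANISM_READTHROUGH_NONCORE}
    positives = [s for s, m in per_species.items() if m in readthrough]
    counts = {m: sum(1 for v in per_species.values() if v == m) for m in MECHANISM_PRIORITY}
    return ConservationSummary(
        group_id=entries[0].group_id,
        per_species=per_species,
        n_readthrough_PTS1=counts[MECHANISM_READTHROUGH],
        n_readthrough_PTS1_noncore=counts[MECHANISM_READTHROUGH_NONCORE],
        n_in_ORF_PTS1=counts[MECHANISM_IN_ORF],
        n_PTS2=counts[MECHANISM_PTS2],
        n_none=counts[MECHANISM_NONE],
        conserved_core_context=all(core_by_species[s] for s in positives),
    )


def read_groups(path: str | Path) -> list[OrthologEntry]:
    """Read an ortholog-group TSV (columns: group_id, species, gene_id,
    protein_aa, stop_codon, flank_nt)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in GROUP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"groups TSV missing columns: {missing}")
    return [
        OrthologEntry(
            group_id=row.group_id,
            species=row.species,
            gene_id=row.gene_id,
            protein_aa=row.protein_aa.upper(),
            stop_codon=row.stop_codon.upper(),
            flank_nt=row.flank_nt.upper().replace("U", "T"),
        )
        for row in df.itertuples()
    ]


def conservation_matrix(
    entries: list[OrthologEntry], config: ScreenConfig | None = None
) -> pd.DataFrame:
    """Long-format mechanism matrix: one row per group x species, plus one
    aggregate row per group (species ``(all)``) carrying the counts and the
    core-context conservation flag."""
    config = config or ScreenConfig()
    by_group: dict[str, list[OrthologEntry]] = {}
    for e in entries:
        by_group.setdefault(e.group_id, []).append(e)
    rows = []
    for gid in sorted(by_group):
        summary = summarize_group(by_group[gid], config)
        for species in sorted(summary.per_species):
            rows.append(
                {
                    "group_id": gid,
                    "species": species,
                    "mechanism_class": summary.per_species[species],
                    "n_readthrough_PTS1": "",
                    "n_readthrough_PTS1_noncore": "",
                    "n_in_ORF_PTS1": "",
                    "n_PTS2": "",
                    "n_none": "",
                    "conserved_core_context": "",
                }
            )
        rows.append(
            {
                "group_id": gid,
                "species": "(all)",
                "mechanism_class": "",
                "n_readthrough_PTS1": summary.n_readthrough_PTS1,
                "n_readthrough_PTS1_noncore": summary.n_readthrough_PTS1_noncore,
                "n_in_ORF_PTS1": summary.n_in_ORF_PTS1,
                "n_PTS2": summary.n_PTS2,
                "n_none": summary.n_none,
                "conserved_core_context": summary.conserved_core_context,
            }
        )
    return pd.DataFrame(rows)


def run_conservation(
    groups_path: str | Path, out_path: str | Path, config: ScreenConfig | None = None
) -> pd.DataFrame:
    """File-to-file conservation stage: groups TSV in, matrix TSV out."""
    entries = read_groups(groups_path)
    df = conservation_matrix(entries, config)
    df.to_csv(out_path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")
    return df
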