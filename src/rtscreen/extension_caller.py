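"""Call the in-frame readthrough extension downstream of an annotated stop.

When a ribosome reads through a stop codon it continues in the same frame
until the next in-frame stop; the peptide appended in between is the
readthrough extension. This module walks the 3' flank codon by codon in the
frame continuing the CDS, stops at the first in-frame stop codon, and
translates the intervening sequence with the standard genetic code.
"""

from __future__ import annotations

from dataclasses import dataclass

STOP_CODONS = ("TAA", "TAG", "TGA")

# Standard genetic code (translation table 1).
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass
class ReadthroughExtension:
    """Extension between the annotated stop and the next in-frame stop.

    ``ext_nt``/``ext_aa`` exclude both stop codons. ``status`` is ``closed``
    (a second in-frame stop was found), ``open`` (the walk ran off the flank
    or hit the length cap first) or ``empty`` (the very first flank codon is
    a stop). A codon containing N translates to 'X' and is never treated as
    a stop.
    """

    ext_nt: str
    ext_aa: str
    status: str  # 'closed' | 'open' | 'empty'
    terminal_stop: str | None  # 'TAA' | 'TAG' | 'TGA' | None


def translate(nt: str) -> str:
    """Translate DNA with the standard code; stops are '*', any codon
    containing N is 'X'. Length must be a multiple of 3."""
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} is not a multiple of 3")
    out = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        out.append("X" if "N" in codon else GENETIC_CODE[codon])
    return "".join(out)


def call_extension(record, max_ext_nt: int = 600) -> ReadthroughExtension:
    """Call the readthrough extension of a gene record's 3' flank.

    The flank is walked codon by codon in the frame that continues the CDS.
    The walk ends at the first codon in {TAA, TAG, TGA} (status ``closed``;
    ``empty`` if that is the very first codon) or after ``max_ext_nt`` /
    flank end (status ``open``, no terminal stop).
    """
    if record.cds_nt[-3:] not in STOP_CODONS:
        raise ValueError(f"record {record.gene_id}: CDS does not end in a stop codon")
    if max_ext_nt <= 0 or max_ext_nt % 3 != 0:
        raise ValueError("max_ext_nt must be a positive multiple of 3")
    return call_extension_nt(record.flank_nt, max_ext_nt)


def call_extension_nt(flank_nt: str, max_ext_nt: int = 600) -> ReadthroughExtension:
    """Extension call on a bare flank sequence (see :func:`call_extension`)."""
    limit = min(len(flank_nt) // 3 * 3, max_ext_nt)
    codons: list[str] = []
    terminal = None
    for i in range(0, limit, 3):
        codon = flank_nt[i : i + 3]
        if codon in STOP_CODONS:  # N-containing codons never terminate
            terminal = codon
            break
        codons.append(codon)
    ext_nt = "".join(codons)
    if terminal is None:
        status = "open"
    elif not codons:
        status = "empty"
    else:
        status = "closed"
    return ReadthroughExtension(
        ext_nt=ext_nt,
        ext_aa=translate(ext_nt),
        status=status,
        terminal_stop=terminal,
    )
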