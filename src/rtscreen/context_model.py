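"""Stop-codon context classification for leaky termination.

Termination efficiency depends on the stop codon and the nucleotides
immediately downstream. Mutational reporter assays in fungi and human cells
established a deliberately ordinal picture: a TGA stop followed by the
dinucleotide CT is the core element sufficient for efficient readthrough
(TAA/TAG at the same context terminate far more tightly), an A at the +3
position further stimulates readthrough, and a G at +4 is enriched among
readthrough genes. No quantitative efficiency scores are modelled here —
the blot-based measurements behind the ranking carry no printed numbers —
so the classification is flag-based: ``core_pass`` is the screen's inclusion
filter, ``plus3_A`` and ``plus4_G`` are enhancer annotations only.
"""

from __future__ import annotations

from dataclasses import dataclass

STOP_CODONS = ("TAA", "TAG", "TGA")

CORE_STOP = "TGA"
CORE_DINUCLEOTIDE = "CT"


@dataclass(frozen=True)
class ContextCall:
    stop_codon: str
    plus1_2: str  # downstream dinucleotide ('' if fewer than 2 nt available)
    plus3: str | None
    plus4: str | None
    core_pass: bool
    plus3_A: bool
    plus4_G: bool


def classify_context(stop_codon: str, downstream: str) -> ContextCall:
    """Classify ``stop_codon`` plus its +1..+4 downstream nucleotides.

    ``core_pass`` is true iff the stop is TGA and the downstream dinucleotide
    is CT; the +3/+4 enhancer flags are only raised on a core-passing context.
    Downstream sequence shorter than 4 nt yields ``None`` for the missing
    positions and false flags.
    """
    if stop_codon not in STOP_CODONS:
        raise ValueError(f"{stop_codon!r} is not a stop codon")
    plus1_2 = downstream[:2] if len(downstream) >= 2 else ""
    plus3 = downstream[2] if len(downstream) >= 3 else None
    plus4 = downstream[3] if len(downstream) >= 4 else None
    core = stop_codon == CORE_STOP and plus1_2 == CORE_DINUCLEOTIDE
    return ContextCall(
        stop_codon=stop_codon,
        plus1_2=plus1_2,
        plus3=plus3,
        plus4=plus4,
        core_pass=core,
        plus3_A=core and plus3 == "A",
        plus4_G=core and plus4 == "G",
    )
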