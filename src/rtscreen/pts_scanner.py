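"""PTS1 / PTS2 motif scanning.

PTS1 (peroxisomal targeting signal type 1) is a C-terminal tripeptide,
prototype SKL, functional only at the extreme C-terminus. Readthrough
extensions are scanned with a regular expression over the rendered peptide
``"*" + extension + "*"`` — the leading ``*`` is the (read-through) annotated
stop, the trailing ``*`` the next in-frame stop — so a hit requires the
tripeptide to sit immediately before the terminal stop:

    ^\\*[^*]*?(ALT1|...|ALT10)\\*

with ten tripeptide alternatives covering 37 distinct tripeptides. The same
tripeptide set also defines the in-ORF C-terminal PTS1 test ("no readthrough"
mechanism). PTS2, the N-terminal nonapeptide route, is covered by an
approximate consensus scan only (R-[LVIQ]-X-X-[LVIH]-[LSGA]-X-[HQ]-[LAF]);
its results are labelled approximate wherever they are reported.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

#: the ten PTS1 tripeptide alternatives, in reporting order
PTS1_ALTERNATIVES = (
    "[ASTPCE]RL",
    "[SATPCVNG]KL",
    "S[SNH]L",
    "ARI",
    "S[KR]M",
    "[AG]NL",
    "SN[IM]",
    "[SA][KRQ]Y",
    "HHL",
    "[QS][KRQ]F",
)

PTS1_PATTERN = r"(^\*[^*]*?(" + "|".join(PTS1_ALTERNATIVES) + r")\*)"
PTS1_REGEX = re.compile(PTS1_PATTERN)

PTS2_PATTERN = r"R[LVIQ]..[LVIH][LSGA].[HQ][LAF]"
PTS2_REGEX = re.compile(PTS2_PATTERN)


@dataclass(frozen=True)
class Pts1Hit:
    tripeptide: str
    motif_alternative: str  # the alternative that matched, e.g. '[SATPCVNG]KL'


@dataclass(frozen=True)
class Pts2Hit:
    nonapeptide: str
    start_offset: int
    approximate: bool = True  # consensus scan, not a trained predictor


def _expand(alternative: str) -> list[str]:
    """Expand one character-class alternative into its tripeptides."""
    classes: list[str] = []
    i = 0
    while i < len(alternative):
        if alternative[i] == "[":
            j = alternative.index("]", i)
            classes.append(alternative[i + 1 : j])
            i = j + 1
        else:
            classes.append(alternative[i])
            i += 1
    assert len(classes) == 3
    return ["".join(t) for t in product(*classes)]


def pts1_tripeptides() -> list[str]:
    """All PTS1 tripeptides in stable reporting order (first alternative
    first, character classes expanded left to right)."""
    seen: list[str] = []
    for alt in PTS1_ALTERNATIVES:
        for tri in _expand(alt):
            if tri not in seen:
                seen.append(tri)
    return seen


def pts1_tripeptide_set() -> frozenset[str]:
    """The set of tripeptides accepted by the PTS1 motif (37 members)."""
    return frozenset(pts1_tripeptides())


def _alternative_for(tripeptide: str) -> str:
    for alt in PTS1_ALTERNATIVES:
        if re.fullmatch(alt, tripeptide):
            return alt
    raise ValueError(f"{tripeptide!r} matches no PTS1 alternative")


def scan_extension_pts1(ext) -> Pts1Hit | None:
    """Scan a readthrough extension for a terminal PTS1.

    The regex is applied to ``"*" + ext_aa + "*"``; only closed extensions
    (ones ending at a genuine in-frame stop) of at least 3 residues can hit,
    and the hit tripeptide is necessarily the extension's last 3 residues.
    """
    if ext.status != "closed" or len(ext.ext_aa) < 3:
        return None
    m = PTS1_REGEX.search("*" + ext.ext_aa + "*")
    if m is None:
        return None
    tri = m.group(2)
    return Pts1Hit(tripeptide=tri, motif_alternative=_alternative_for(tri))


def scan_orf_terminal_pts1(protein_aa: str) -> Pts1Hit | None:
    """Test whether a regular ORF already ends in a PTS1 tripeptide
    (peroxisomal targeting without readthrough)."""
    if len(protein_aa) < 3:
        return None
    tri = protein_aa[-3:]
    if tri not in pts1_tripeptide_set():
        return None
    return Pts1Hit(tripeptide=tri, motif_alternative=_alternative_for(tri))


def scan_pts2(protein_aa: str, window: int = 40) -> Pts2Hit | None:
    """Approximate PTS2 consensus scan over the N-terminal ``window``.

    The nonapeptide must start within the first ``window`` residues. This is
    a documented consensus, not a trained targeting predictor; hits are
    flagged approximate.
    """
    if window <= 0:
        return None
    m = PTS2_REGEX.search(protein_aa[: window + 8])
    if m is None or m.start() >= window:
        return None
    return Pts2Hit(nonapeptide=m.group(0), start_offset=m.start())
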