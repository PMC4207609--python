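# Methods

## The screen

The screen looks for genes that can produce a peroxisomal isoform through
stop-codon readthrough. For each annotated protein-coding gene it computes
three things and combines them into one mechanism call:

1. **Stop-codon context.** The stop codon plus the +1..+4 downstream
   nucleotides are classified against the leaky-termination element: the
   *core* element is a TGA stop followed by the dinucleotide CT; an A at +3
   stimulates readthrough further and a G at +4 is enriched among
   readthrough genes. The model is deliberately ordinal and flag-based
   (`core_pass`, `plus3_A`, `plus4_G`) rather than a quantitative efficiency
   score: the underlying mutational evidence is blot-based relative ranking
   without usable numeric values, so inventing weights would add precision
   that is not there. The screen's inclusion filter is `core_pass` alone;
   the +3/+4 flags are annotations. The enhancer flags are defined only on
   a core-passing context — on a tight TAA/TAG context a downstream A is not
   evidence of anything.
2. **Readthrough extension.** The 3' flank is walked codon by codon in the
   frame continuing the CDS until the first codon in {TAA, TAG, TGA}. The
   nucleotides in between are the extension; translation uses the standard
   genetic code. Extension status is `closed` (second stop found), `empty`
   (the very first flank codon is a stop) or `open` (cap or end of flank
   reached first). Only closed extensions are eligible for PTS1 calling,
   because a C-terminal targeting signal does not exist until the C-terminus
   does.
3. **PTS1 scan.** The translated extension is rendered as
   `"*" + extension + "*"` (both stops as `*`) and matched against the
   tripeptide motif regex (ten alternatives; 37 tripeptides when expanded).
   Because the alternative must be followed directly by the terminal `*`,
   a hit is necessarily the extension's last three residues. The same
   37-tripeptide set defines the in-ORF C-terminal test that detects
   peroxisomal targeting requiring no readthrough at all.

Mechanism classes are assigned with a fixed priority when several signals
coexist: `readthrough_PTS1` (core context + extension PTS1) >
`readthrough_PTS1_noncore_context` (extension PTS1 behind a non-core
context; reported only under `context_mode="any"`) > `in_ORF_PTS1` > `PTS2`
(if enabled) > `none`. The priority ordering is a package design choice; the
mechanisms are biologically alternatives with no inherent tie rule. All
genes are reported with a filterable mechanism column rather than emitting
only the TGA-CT hits, because conservation analysis needs the
non-readthrough mechanisms at the same loci.

## Input handling

GFF3 is 1-based inclusive on disk and converted exactly once to 0-based
half-open coordinates at parse time; all internal arithmetic uses the
internal convention, which keeps off-by-one errors at a single boundary.
Minus-strand genes are reverse-complemented so CDS and flank both read 5'→3'
in the coding sense. When a gene has several mRNAs the transcript with the
longest total CDS is used, ties broken by the lexicographically smallest
transcript id — annotation sets carry no preferred-isoform marker, and the
rule must be deterministic. Genes whose CDS length is not a multiple of 3 or
that lack a terminal stop are skipped with a warning and counted in the run
summary; annotation errors must not poison the screen.

The 3' flank is the spliced 3' UTR when `three_prime_UTR` features exist
(`flank_source=spliced_utr`), else `flank_len` nt of raw genomic sequence
(`flank_source=genomic`, truncated at the contig edge with a flag). Spliced
UTRs win because an intron inside a genomic flank would corrupt the reading
frame of the extension; both paths are labelled rather than guessed at.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `flank_len` | 600 nt | 3' flank retrieved per gene; generous for the short (tens of residues) extensions this mechanism produces while bounding work |
| `max_ext_nt` | 600 nt (200 codons) | cap on the extension walk; keeps degenerate stop-free flanks cheap |
| `context_mode` | `tga-ct` | inclusion filter; `any` additionally reports non-core PTS1 extensions as low-confidence candidates |
| `include_pts2` | off | approximate N-terminal PTS2 consensus scan |
| PTS2 window | 40 aa | N-terminal region in which the nonapeptide may start |

A flank shorter than the extension cap only warns: the extension is then
limited by the flank, which is a property of the input, not an error.

Codons containing N translate to `X` and are never treated as stop codons;
`X` can never participate in a PTS1 hit (the tripeptide classes exclude it),
so ambiguity is conservative in both directions. A flank shorter than one
codon yields a length-0 extension with `status=open` (the extension runs off
the available data); `empty` is reserved for an immediate in-frame stop.

## PTS2

PTS2 prediction proper is a trained external predictor's job; this package
ships only a consensus scan (R-[LVIQ]-X-X-[LVIH]-[LSGA]-X-[HQ]-[LAF] within
the N-terminal window) so that mechanism matrices can express the PTS2 route.
Every PTS2 hit is flagged `approximate=True` and the class is off by default.

## Conservation stage

Ortholog groups arrive precomputed (orthology inference is a different
project); each entry carries the regular ORF translation, the stop codon and
the 3' flank, and is classified with the identical code path as the genome
screen — this identity is asserted by a cross-module consistency test. A
species present more than once in a group keeps its best-priority mechanism.
"Conservation" means presence/absence tabulation across the provided
species; no tree inference or ancestral-state reconstruction is attempted.
`conserved_core_context` is true when every readthrough-positive species in
the group carries the TGA CT element. Because two extra mechanism classes
exist under `context_mode="any"`/PTS2, the summary carries five counts
(`n_readthrough_PTS1`, `n_readthrough_PTS1_noncore`, `n_in_ORF_PTS1`,
`n_PTS2`, `n_none`) so they always sum to the number of species.

## Synthetic genomes

The simulator emulates exactly the statistical structure the screen assumes:
protein-coding genes (uniform sense-codon bodies with no internal in-frame
stop), a terminal stop, a downstream region, and four planted classes —
readthrough-PTS1 genes (TGA, +1..+3 = CTA, an extension of 5–30 codons
ending in a tripeptide drawn uniformly from the PTS1 set, then a second
stop), context-only decoys (TGA CT, PTS1-free extension), wrong-stop decoys
(TAA/TAG + CTA + PTS1 extension) and in-ORF-PTS1 decoys. Defaults are a
200-gene genome, 10 genes per planted class, CDS 100–300 codons, intergenic
spacers 80–200 nt, half the genes on the minus strand.

Clean negatives are enforced by **rejection sampling at generation time**,
not post-hoc filtering: a background flank is resampled until its first
in-frame extension (a) closes inside the gene's own intergenic spacer, so
the call cannot depend on the neighbouring gene, (b) does not end in a PTS1
tripeptide, and (c) does not sit behind a TGA CT context; background ORF
termini are likewise resampled out of the PTS1 set (the latter goes slightly
beyond flank rejection so that *every* class, not just readthrough calls, is
exactly predictable from the truth table). Without rejection, ~0.46% of
random tripeptides (37/8000) and 1/192 of random stop contexts would
contaminate the background stochastically. Consequently planted-truth
recovery is exact by construction — the acceptance test asserts sensitivity
and specificity of 1 — and what such tests demonstrate is the correctness of
the pipeline's bookkeeping (coordinates, strands, frames, motif semantics),
**not** the screen's error rate on real genomes, where true readthrough
genes are not guaranteed clean flanks, annotations contain errors, and PTS1
tripeptides occur by chance and must be filtered by conservation. Codon
usage is uniform over sense codons (the screen is codon-usage-agnostic), and
no realistic UTR length distributions, introns in simulated genes, or
readthrough-efficiency signal are emulated.

Problem sizes used by the shipped checks: the routine suite screens 50-gene
genomes plus 25 all-background genomes of 60 genes; the acceptance checks
use the full 200-gene default. All are chosen as comfortably representative
for an exact-recovery pipeline whose behaviour does not change with scale.

## Determinism

One seed drives the simulator; the same seed yields byte-identical
FASTA/GFF3/truth files. The screen itself has no randomness; report rows are
sorted by contig and coordinate and re-runs produce byte-identical TSVs.

## Known limitations

* No quantitative readthrough-efficiency prediction, near-cognate tRNA
  identity, downstream mRNA secondary-structure stimulators, or
  oxygen-dependent regulation of termination fidelity.
* Selenocysteine recoding of UGA is not modelled.
* One transcript per gene; no trans-splicing, polycistronic transcripts, or
  transcript reconstruction from RNA-seq.
* The PTS1 call is the motif regex alone — no physicochemical context
  scoring or receptor-binding model; a hook for an external scorer is the
  natural extension point.
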