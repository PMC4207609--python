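# rtscreen

Genome-wide screen for **stop-codon readthrough-derived peroxisomal protein
isoforms**.

Translation usually terminates at the annotated stop codon, but some stop
contexts are leaky: a near-cognate tRNA occasionally decodes the stop and the
ribosome continues in frame to the next stop codon, appending a hidden
C-terminal extension to the protein. A UGA stop followed by the dinucleotide
CU is such a leaky element (an A at +3 further stimulates readthrough, and a
G at +4 is enriched among readthrough genes). When the resulting extension
ends in a **PTS1** — a C-terminal tripeptide, prototype Ser-Lys-Leu (SKL),
that is functional only at the extreme C-terminus — the readthrough isoform
is imported into peroxisomes, giving metabolic enzymes such as malate and
lactate dehydrogenase a dual cytosolic/peroxisomal localization.

`rtscreen` is for computational biologists who want to run this screen on an
annotated genome, or to study the screen's behaviour under controlled
conditions. It provides:

* **`rtscreen scan`** — screen a genome (FASTA + GFF3): for every
  protein-coding gene, classify the stop-codon context (core filter:
  stop = TGA and +1/+2 = CT), call the in-frame extension from the annotated
  stop to the next in-frame stop, translate it, and scan it for a terminal
  PTS1 with the tripeptide motif

  ```
  ^\*[^*]*?([ASTPCE]RL|[SATPCVNG]KL|S[SNH]L|ARI|S[KR]M|[AG]NL|SN[IM]|[SA][KRQ]Y|HHL|[QS][KRQ]F)\*
  ```

  applied to `"*" + extension + "*"` (37 tripeptides in total). Each gene
  gets one mechanism class: `readthrough_PTS1`, `in_ORF_PTS1` (the PTS1 is
  already part of the regular ORF — no readthrough needed), optionally
  `readthrough_PTS1_noncore_context` (PTS1 extension behind a non-TGA-CT
  context, reported only under `--context any`) and `PTS2` (approximate
  N-terminal consensus scan, off by default), or `none`.
* **`rtscreen conserve`** — classify precomputed ortholog groups (TSV of
  protein C-terminus, stop codon and 3' flank per species) with exactly the
  same machinery, and tabulate the per-species mechanism matrix of a gene
  family.
* **`rtscreen simulate`** — generate synthetic genomes with planted
  readthrough-PTS1 genes, decoys (PTS1 behind the wrong stop, core context
  without PTS1, in-ORF PTS1) and rejection-sampled clean background, plus a
  truth table, so the whole pipeline is testable without downloads.

## Worked example

```python
from rtscreen import GeneRecord, ScreenConfig, classify_record

rec = GeneRecord(
    gene_id="tpi1_like", contig="chr1", strand="+", start=0,
    cds_nt="ATGTGA",                  # CDS ending in the annotated TGA stop
    flank_nt="CTATCGAAGCTTTAG",       # 3' flank downstream of that stop
    flank_source="genomic",
)
report = classify_record(rec, ScreenConfig())
print(report.extension.ext_aa, report.extension.status)
print(report.context.core_pass, report.context.plus3_A)
print(report.pts1)
print(report.mechanism_class)
```

prints

```
LSKL closed
True True
Pts1Hit(tripeptide='SKL', motif_alternative='[SATPCVNG]KL')
readthrough_PTS1
```

Read: the flank `CTA TCG AAG CTT | TAG` encodes the in-frame extension
peptide `LSKL`, closed by a second stop (TAG). The stop context passes the
core filter (TGA followed by CT) with the stimulating A at +3, the extension
ends in the prototypical PTS1 `SKL`, so the gene is called a
readthrough-derived peroxisomal isoform candidate.

The same from the shell, on a simulated genome:

```bash
$ rtscreen simulate --n-genes 40 --planted 4 --decoys 4 --seed 3 --out-prefix sim
wrote sim.fa, sim.gff3, sim.truth.tsv (40 genes)
$ rtscreen scan --genome sim.fa --gff sim.gff3 --out candidates.tsv
scanned 40 genes (skipped 0): 4 readthrough_PTS1, 4 in_ORF_PTS1
```

`candidates.tsv` has one row per gene (sorted by contig and coordinate) with
the stop codon, the +1..+4 context and its flags, the extension peptide and
status, the PTS1/in-ORF hits, and the mechanism class; a machine-readable run
summary is written next to it as `candidates.tsv.summary.json`.

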