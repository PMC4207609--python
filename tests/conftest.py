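"""Shared fixtures: a hand-built toy genome/annotation and simulated genomes."""

from __future__ import annotations

import pytest

from rtscreen import ScreenConfig, SimConfig, simulate_genome

# Hand-assembled contigs. Coordinates in the GFF below are 1-based inclusive.
TOY_CONTIGS = {
    # geneA (+): CDS ATG AAA CCC TGA at [0,12), downstream CTATCGAAGCTTTAGGGGGG
    "toy1": "ATGAAACCCTGA" + "CTATCGAAGCTTTAG" + "GGGGG",
    # geneB (-): sense unit = CDS ATGTTTGGATAA + sense flank AAAGCT,
    # reverse-complemented and placed at [2,20)
    "toy2": "CC" + "AGCTTTTTATCCAAACAT" + "TT",
    # geneC (+): CDS ATG CCC TGA with only 4 nt left on the contig
    "toy3": "ATGCCCTGA" + "ACGT",
    # geneD (+): CDS ATG GGG TGA, spliced 3' UTR = CTATCG + AAGCTT around an
    # intron GTAAGT
    "toy4": "ATGGGGTGA" + "CTATCG" + "GTAAGT" + "AAGCTT" + "TAGAAA",
    # geneE: CDS length 10 (not a multiple of 3); geneF: CDS lacks a stop
    "toy5": "ATGAAACCCT" + "AAAAAAAAAA" + "ATGAAACCC" + "TTTT",
    # geneG: two mRNAs, long CDS [0,18) wins over short CDS [12,18)
    "toy6": "ATGAAACCCAAATTTTGA" + "CCCCCC",
    # geneH: two mRNAs with equal-length CDS; smaller transcript id wins
    "toy7": "ATGAAACCCTGA" + "AAAAAA",
}

TOY_GFF = """##gff-version 3
toy1\ttoy\tgene\t1\t12\t.\t+\t.\tID=geneA
toy1\ttoy\tmRNA\t1\t12\t.\t+\t.\tID=geneA.t1;Parent=geneA
toy1\ttoy\tCDS\t1\t12\t.\t+\t0\tID=geneA.t1.cds;Parent=geneA.t1
toy2\ttoy\tgene\t9\t20\t.\t-\t.\tID=geneB
toy2\ttoy\tmRNA\t9\t20\t.\t-\t.\tID=geneB.t1;Parent=geneB
toy2\ttoy\tCDS\t9\t20\t.\t-\t0\tID=geneB.t1.cds;Parent=geneB.t1
toy3\ttoy\tgene\t1\t9\t.\t+\t.\tID=geneC
toy3\ttoy\tmRNA\t1\t9\t.\t+\t.\tID=geneC.t1;Parent=geneC
toy3\ttoy\tCDS\t1\t9\t.\t+\t0\tID=geneC.t1.cds;Parent=geneC.t1
toy4\ttoy\tgene\t1\t27\t.\t+\t.\tID=geneD
toy4\ttoy\tmRNA\t1\t27\t.\t+\t.\tID=geneD.t1;Parent=geneD
toy4\ttoy\tCDS\t1\t9\t.\t+\t0\tID=geneD.t1.cds;Parent=geneD.t1
toy4\ttoy\tthree_prime_UTR\t10\t15\t.\t+\t.\tID=geneD.t1.utr1;Parent=geneD.t1
toy4\ttoy\tthree_prime_UTR\t22\t27\t.\t+\t.\tID=geneD.t1.utr2;Parent=geneD.t1
toy5\ttoy\tgene\t1\t10\t.\t+\t.\tID=geneE
toy5\ttoy\tmRNA\t1\t10\t.\t+\t.\tID=geneE.t1;Parent=geneE
toy5\ttoy\tCDS\t1\t10\t.\t+\t0\tID=geneE.t1.cds;Parent=geneE.t1
toy5\ttoy\tgene\t21\t29\t.\t+\t.\tID=geneF
toy5\ttoy\tmRNA\t21\t29\t.\t+\t.\tID=geneF.t1;Parent=geneF
toy5\ttoy\tCDS\t21\t29\t.\t+\t0\tID=geneF.t1.cds;Parent=geneF.t1
toy6\ttoy\tgene\t1\t18\t.\t+\t.\tID=geneG
toy6\ttoy\tmRNA\t1\t18\t.\t+\t.\tID=geneG.t_long;Parent=geneG
toy6\ttoy\tCDS\t1\t18\t.\t+\t0\tID=geneG.t_long.cds;Parent=geneG.t_long
toy6\ttoy\tmRNA\t13\t18\t.\t+\t.\tID=geneG.t_short;Parent=geneG
toy6\ttoy\tCDS\t13\t18\t.\t+\t0\tID=geneG.t_short.cds;Parent=geneG.t_short
toy7\ttoy\tgene\t1\t12\t.\t+\t.\tID=geneH
toy7\ttoy\tmRNA\t1\t12\t.\t+\t.\tID=geneH.t_b;Parent=geneH
toy7\ttoy\tCDS\t1\t12\t.\t+\t0\tID=geneH.t_b.cds;Parent=geneH.t_b
toy7\ttoy\tmRNA\t1\t12\t.\t+\t.\tID=geneH.t_a;Parent=geneH
toy7\ttoy\tCDS\t1\t12\t.\t+\t0\tID=geneH.t_a.cds;Parent=geneH.t_a
"""


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory):
    """Paths of the toy FASTA and GFF3 on disk."""
    d = tmp_path_factory.mktemp("toy")
    fasta = d / "toy.fa"
    gff = d / "toy.gff3"
    fasta.write_text("".join(f">{cid}\n{seq}\n" for cid, seq in TOY_CONTIGS.items()))
    gff.write_text(TOY_GFF)
    return fasta, gff


@pytest.fixture(scope="session")
def small_sim():
    """50-gene simulated genome with 3 genes per planted class."""
    return simulate_genome(
        SimConfig(
            n_genes=50,
            n_planted_readthrough_pts1=3,
            n_decoy_context_only=3,
            n_decoy_pts1_wrong_stop=3,
            n_decoy_in_orf_pts1=3,
            seed=11,
        )
    )


@pytest.fixture(scope="session")
def sim200():
    """Full-size simulated genome: 200 genes, 10 per planted class."""
    return simulate_genome(SimConfig(seed=42))


@pytest.fixture
def any_context_config():
    return ScreenConfig(context_mode="any")
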