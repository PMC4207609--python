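"""End-to-end screen behaviour on simulated genomes and single records."""

import pytest

from rtscreen import (
    GeneModel,
    GeneRecord,
    GenomeMap,
    ScreenConfig,
    classify_record,
    run_screen,
    run_summary,
    screen_genome,
)
from rtscreen.sequence_io import _revcomp


def _truth_sets(sim):
    by_class = {}
    for row in sim.truth.itertuples():
        by_class.setdefault(row.planted_class, set()).add(row.gene_id)
    return by_class


def _mechanisms(reports):
    return {r.gene_id: r.mechanism_class for r in reports}


class TestMechanismClassification:
    def test_worked_example_readthrough_pts1(self):
        rec = GeneRecord("g", "c", "+", 0, "ATGTGA", "CTATCGAAGCTTTAG", "genomic")
        rep = classify_record(rec, ScreenConfig())
        assert rep.extension.ext_aa == "LSKL"
        assert rep.context.core_pass and rep.context.plus3_A
        assert rep.pts1.tripeptide == "SKL"
        assert rep.mechanism_class == "readthrough_PTS1"

    def test_pts1_behind_wrong_stop_needs_any_mode(self):
        # TAA + CTA + extension ending SKL: a decoy for the core filter
        rec = GeneRecord("g", "c", "+", 0, "ATGTAA", "CTATCGAAGCTTTAG", "genomic")
        assert classify_record(rec, ScreenConfig()).mechanism_class == "none"
        rep = classify_record(rec, ScreenConfig(context_mode="any"))
        assert rep.mechanism_class == "readthrough_PTS1_noncore_context"

    def test_in_orf_pts1_without_readthrough(self):
        # annotated protein ends ...SKL before a TAA stop
        rec = GeneRecord("g", "c", "+", 0, "ATGTCGAAGCTTTAA", "GGGGGGTAA", "genomic")
        rep = classify_record(rec, ScreenConfig())
        assert rep.orf_terminal_pts1.tripeptide == "SKL"
        assert rep.mechanism_class == "in_ORF_PTS1"

    def test_readthrough_outranks_in_orf(self):
        # both signals present: readthrough PTS1 has priority
        rec = GeneRecord("g", "c", "+", 0, "ATGTCGAAGCTTTGA", "CTATCGAAGCTTTAG", "genomic")
        rep = classify_record(rec, ScreenConfig())
        assert rep.pts1 and rep.orf_terminal_pts1
        assert rep.mechanism_class == "readthrough_PTS1"

    def test_open_extension_is_ineligible_for_pts1(self):
        rec = GeneRecord("g", "c", "+", 0, "ATGTGA", "CTATCGAAGCTT", "genomic")
        rep = classify_record(rec, ScreenConfig())
        assert rep.extension.status == "open"
        assert rep.pts1 is None and rep.mechanism_class == "none"

    def test_pts2_only_when_enabled(self):
        cds = "ATG" + "CGTCTAGCCGTACTATCAGGCCATCTT" + "TAA"  # MRLAVLSGHL...
        rec = GeneRecord("g", "c", "+", 0, cds, "GGGTAA", "genomic")
        assert classify_record(rec, ScreenConfig()).mechanism_class == "none"
        rep = classify_record(rec, ScreenConfig(include_pts2=True))
        assert rep.pts2 is not None and rep.mechanism_class == "PTS2"


class TestScreenOnSimulatedGenome:
    def test_planted_truth_recovered_exactly(self, small_sim, any_context_config):
        truth = _truth_sets(small_sim)
        mech = _mechanisms(screen_genome(small_sim.genome, small_sim.models, any_context_config))
        assert {g for g, m in mech.items() if m == "readthrough_PTS1"} == truth["readthrough_PTS1"]
        assert {
            g for g, m in mech.items() if m == "readthrough_PTS1_noncore_context"
        } == truth["pts1_wrong_stop"]
        assert {g for g, m in mech.items() if m == "in_ORF_PTS1"} == truth["in_orf_pts1"]
        for g in truth["context_only"] | truth["background"]:
            assert mech[g] == "none"

    def test_core_filter_excludes_wrong_stop_decoys(self, small_sim):
        truth = _truth_sets(small_sim)
        mech = _mechanisms(screen_genome(small_sim.genome, small_sim.models, ScreenConfig()))
        assert {g for g, m in mech.items() if m == "readthrough_PTS1"} == truth["readthrough_PTS1"]
        for g in truth["pts1_wrong_stop"]:
            assert mech[g] == "none"

    def test_strand_invariance(self, small_sim, any_context_config):
        genome, models = small_sim.genome, small_sim.models
        flipped = GenomeMap({c: _revcomp(s) for c, s in genome.contigs.items()})
        fmodels = [
            GeneModel(
                m.gene_id,
                m.contig,
                "-" if m.strand == "+" else "+",
                [(len(genome[m.contig]) - e, len(genome[m.contig]) - s) for s, e in m.cds_segments],
            )
            for m in models
        ]
        fwd = _mechanisms(screen_genome(genome, models, any_context_config))
        rev = _mechanisms(screen_genome(flipped, fmodels, any_context_config))
        assert fwd == rev

    def test_run_summary_tallies(self, small_sim):
        reports = screen_genome(small_sim.genome, small_sim.models, ScreenConfig())
        summary = run_summary(reports)
        assert summary["n_genes_scanned"] == 50
        assert summary["mechanism_counts"]["readthrough_PTS1"] == 3
        assert sum(summary["mechanism_counts"].values()) == 50
        # planted + context-only decoys all carry the TGA CT core context
        assert summary["n_core_context"] == 6


class TestFileInterface:
    def test_rerun_is_byte_identical(self, tmp_path, small_sim):
        fa, gff, _ = small_sim.write(tmp_path / "sim")
        out1, out2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        run_screen(fa, gff, out1)
        run_screen(fa, gff, out2)
        assert out1.read_bytes() == out2.read_bytes()
        header = out1.read_text().splitlines()[0].split("\t")
        assert header[:4] == ["gene_id", "contig", "strand", "stop_codon"]
        assert "mechanism_class" in header

    def test_summary_json_written(self, tmp_path, small_sim):
        fa, gff, _ = small_sim.write(tmp_path / "sim")
        out = tmp_path / "cand.tsv"
        summary = run_screen(fa, gff, out)
        assert (tmp_path / "cand.tsv.summary.json").exists()
        assert summary["n_genes_scanned"] == 50

    def test_no_parseable_genes_is_hard_error(self, tmp_path):
        genome = GenomeMap({"c": "ATGAAACCC" * 5})
        models = [GeneModel("g1", "c", "+", [(0, 9)])]  # no terminal stop
        with pytest.raises(RuntimeError, match="no well-formed genes"):
            screen_genome(genome, models, ScreenConfig())


class TestScreenConfig:
    def test_rejects_bad_values(self):
        with pytest.raises(ValueError):
            ScreenConfig(flank_len=0)
        with pytest.raises(ValueError):
            ScreenConfig(context_mode="everything")

    def test_flank_shorter_than_cap_warns_only(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="rtscreen"):
            ScreenConfig(flank_len=300, max_ext_nt=600)
        assert any("flank_len" in r.message for r in caplog.records)
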