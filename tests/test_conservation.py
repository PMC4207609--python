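"""Per-ortholog mechanism classification and group conservation summaries."""

import pytest

from rtscreen import (
    OrthologEntry,
    ScreenConfig,
    build_gene_records,
    classify_entry,
    conservation_matrix,
    read_groups,
    run_conservation,
    screen_genome,
    summarize_group,
    translate,
)

MOTIF_FREE_FLANK = "GGTGGAGGTTAA"  # extension GGG, closed, no PTS1


def _entry(species, protein="MAAAA", stop="TAA", flank=MOTIF_FREE_FLANK, group="og1"):
    return OrthologEntry(group, species, f"{species}_gene", protein, stop, flank)


class TestClassifyEntry:
    def test_readthrough_pts1(self):
        e = _entry("sp1", stop="TGA", flank="CTATCGAAGCTTTAG")
        assert classify_entry(e) == "readthrough_PTS1"

    def test_in_orf_pts1(self):
        # protein ends SRL ([ASTPCE]RL) with a tight TAA stop and motif-free flank
        e = _entry("sp1", protein="MAASRL")
        assert classify_entry(e) == "in_ORF_PTS1"

    def test_neither_signal_is_none(self):
        assert classify_entry(_entry("sp1")) == "none"

    def test_empty_flank_falls_back_to_orf_terminus(self):
        assert classify_entry(_entry("sp1", protein="MAASKL", flank="")) == "in_ORF_PTS1"
        assert classify_entry(_entry("sp1", flank="")) == "none"

    def test_invalid_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            _entry("sp1", stop="ATG")


class TestSummarizeGroup:
    def test_mixed_mechanisms_counted(self):
        entries = [
            _entry("sp1", stop="TGA", flank="CTATCGAAGCTTTAG"),
            _entry("sp2", stop="TGA", flank="CTAAGCAAGCTTTAA"),
            _entry("sp3", stop="TGA", flank="CTATCGAAGCTGTAG"),
            _entry("sp4", protein="MAASRL"),
        ]
        s = summarize_group(entries)
        assert (s.n_readthrough_PTS1, s.n_in_ORF_PTS1, s.n_none) == (3, 1, 0)
        assert s.per_species["sp4"] == "in_ORF_PTS1"
        assert s.conserved_core_context  # all 3 positives share TGA CT
        total = (
            s.n_readthrough_PTS1
            + s.n_readthrough_PTS1_noncore
            + s.n_in_ORF_PTS1
            + s.n_PTS2
            + s.n_none
        )
        assert total == 4

    def test_single_species_group(self):
        s = summarize_group([_entry("sp1")])
        assert s.n_none == 1 and s.per_species == {"sp1": "none"}

    def test_duplicate_species_keeps_best_priority(self):
        entries = [
            _entry("sp1"),
            _entry("sp1", stop="TGA", flank="CTATCGAAGCTTTAG"),
        ]
        s = summarize_group(entries)
        assert s.per_species["sp1"] == "readthrough_PTS1"

    def test_empty_group_is_hard_error(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_group([])

    def test_mixed_group_ids_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            summarize_group([_entry("sp1", group="og1"), _entry("sp2", group="og2")])


def test_cross_module_consistency_with_screen(small_sim, any_context_config):
    """An ortholog entry assembled from a screened gene must get the same
    mechanism class as the genome screen gave that gene."""
    records = build_gene_records(
        small_sim.genome, small_sim.models, any_context_config.flank_len
    )
    screen_mech = {
        r.gene_id: r.mechanism_class
        for r in screen_genome(small_sim.genome, small_sim.models, any_context_config)
    }
    for rec in records:
        entry = OrthologEntry(
            group_id="og",
            species=rec.gene_id,
            gene_id=rec.gene_id,
            protein_aa=translate(rec.cds_nt[:-3]),
            stop_codon=rec.stop_codon,
            flank_nt=rec.flank_nt,
        )
        assert classify_entry(entry, any_context_config) == screen_mech[rec.gene_id]


class TestGroupFiles:
    def _write_groups(self, path):
        rows = [
            "group_id\tspecies\tgene_id\tprotein_aa\tstop_codon\tflank_nt",
            "og1\tsp1\tg1\tMAAAA\tTGA\tCTATCGAAGCTTTAG",
            "og1\tsp2\tg2\tMAASRL\tTAA\t" + MOTIF_FREE_FLANK,
            "og2\tsp1\tg3\tMAAAA\tTAA\t" + MOTIF_FREE_FLANK,
        ]
        path.write_text("\n".join(rows) + "\n")

    def test_matrix_has_species_and_aggregate_rows(self, tmp_path):
        groups = tmp_path / "groups.tsv"
        self._write_groups(groups)
        df = run_conservation(groups, tmp_path / "matrix.tsv")
        assert (tmp_path / "matrix.tsv").exists()
        og1 = df[df.group_id == "og1"]
        assert set(og1.species) == {"sp1", "sp2", "(all)"}
        agg = og1[og1.species == "(all)"].iloc[0]
        assert agg.n_readthrough_PTS1 == 1 and agg.n_in_ORF_PTS1 == 1

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("group_id\tspecies\nog1\tsp1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_groups(bad)

    def test_matrix_from_entries_orders_groups(self):
        df = conservation_matrix([_entry("sp1", group="og2"), _entry("sp1", group="og1")])
        assert list(df.group_id) == ["og1", "og1", "og2", "og2"]
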