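"""Summaries, coordinate exports, and the end-to-end pipeline driver."""

import filecmp
import json

import pytest

from synmap import (
    PipelineConfig,
    SpeciesInput,
    ToleranceRule,
    detect_blocks,
    export_blocks_bed,
    export_circos_links,
    percent,
    reference_assembly_summary,
    run_pipeline,
    simulate,
    summarize_blocks,
)
from synmap.map_io import ChromosomeSet
from conftest import anchor, map_for, noise_free_config, sizes_for


def make_blocks(spans, lg_length=100.0, chrom_length=10_000_000):
    """Blocks from ascending anchor runs with the given (bp_start, bp_end,
    n_loci) tuples, separated by chromosome to keep them independent."""
    anchors = []
    for i, (lo, hi, n) in enumerate(spans):
        chrom = f"c{i + 1}"
        for k in range(n):
            bp = lo + (hi - lo) * k // (n - 1)
            anchors.append(
                anchor(f"B{i}L{k}", 10.0 * i + k, bp, chrom=chrom)
            )
    lmap = map_for(anchors, lg_length=lg_length)
    chroms = tuple(f"c{i + 1}" for i in range(len(spans)))
    sizes = sizes_for(chrom_length, chroms=chroms)
    return detect_blocks(anchors, lmap, sizes, ToleranceRule()), sizes["sp"]


class TestSummaries:
    def test_totals_and_proportion(self):
        # 1 Mb + 2 Mb of blocks on a 10 Mb genome
        blocks, _ = make_blocks([(1, 1_000_001, 2), (1, 2_000_001, 2)])
        sizes = ChromosomeSet("sp", {"c1": 5_000_000, "c2": 5_000_000})
        s = summarize_blocks(blocks, sizes, map_total_cM=100.0, n_anchors=4)
        assert s.total_comparison_block_size_mb == pytest.approx(3.0)
        assert s.proportion_genome_in_blocks == pytest.approx(0.3)

    def test_mean_loci_per_block(self):
        blocks, sizes = make_blocks([(1, 500_000, 2), (1, 900_000, 4)])
        s = summarize_blocks(blocks, sizes, 100.0, n_anchors=6)
        assert s.mean_loci_per_block == 3.0

    def test_empty_blocks_zero_filled(self):
        sizes = ChromosomeSet("sp", {"c1": 1000})
        s = summarize_blocks([], sizes, 100.0, n_anchors=0)
        assert s.n_blocks == 0 and s.proportion_genome_in_blocks == 0.0

    def test_matches_brute_force_on_simulation(self):
        sim = simulate(noise_free_config(21))
        sp = sim.species[0]
        from conftest import run_analysis

        _, _, per_sp = run_analysis(sim)
        blocks = per_sp[sp]["blocks"]
        s = summarize_blocks(
            blocks, sim.chromosomes[sp],
            sim.linkage_map.total_length, len(per_sp[sp]["anchors"]),
        )
        bp_spans = [b.genome_span_bp[1] - b.genome_span_bp[0] for b in blocks]
        cm_spans = [b.map_span_cM[1] - b.map_span_cM[0] for b in blocks]
        assert s.n_blocks == len(blocks)
        assert s.total_comparison_block_size_mb == pytest.approx(sum(bp_spans) / 1e6)
        assert s.mean_map_block_size_cm == pytest.approx(
            sum(cm_spans) / len(blocks)
        )
        assert s.proportion_genome_in_blocks == pytest.approx(
            sum(bp_spans) / sim.chromosomes[sp].total_bp
        )
        assert 0 <= s.proportion_map_in_blocks <= 1

    def test_percent_rounding(self):
        assert percent(278, 2275) == 12.2
        assert percent(62, 227) == 27.3

    def test_reference_summary_arithmetic(self):
        ref = reference_assembly_summary(33_865, 9_638_003, 810e6)
        assert ref["mean_contig_size_bp"] == 284.6
        assert ref["genome_coverage_percent"] == 1.19


class TestExports:
    def test_bed_is_zero_based_half_open(self, tmp_path):
        blocks, _ = make_blocks([(100, 500, 2)])
        out = tmp_path / "b.bed"
        export_blocks_bed(blocks, out)
        chrom, start, end, name, score, strand = (
            out.read_text().strip().split("\t")
        )
        assert (start, end) == ("99", "500")
        assert strand == "+"

    def test_bed_strand_from_orientation(self, tmp_path):
        anchors = [anchor("A", 0.0, 500), anchor("B", 5.0, 100)]
        blocks = detect_blocks(
            anchors, map_for(anchors), sizes_for(), ToleranceRule()
        )
        out = tmp_path / "b.bed"
        export_blocks_bed(blocks, out)
        assert out.read_text().strip().split("\t")[5] == "-"

    def test_circos_line_per_block(self, tmp_path):
        blocks, _ = make_blocks([(1, 9000, 3), (1, 5000, 2)])
        out = tmp_path / "links.txt"
        export_circos_links(blocks, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) == len(blocks)
        fields = lines[0].split()
        assert fields[0].startswith("lg") and fields[6].startswith("color=")

    def test_empty_exports(self, tmp_path):
        export_circos_links([], tmp_path / "links.txt")
        assert (tmp_path / "links.txt").read_text() == ""


class TestPipeline:
    @pytest.fixture
    def sim_dir(self, tmp_path):
        sim = simulate(noise_free_config(31, n_transcripts=20))
        paths = sim.write(tmp_path / "data")
        return sim, paths, tmp_path

    def config_for(self, sim, paths, outdir):
        return PipelineConfig(
            map_path=paths["map"],
            species=[
                SpeciesInput(
                    name=sp,
                    chrom_sizes=paths[f"{sp}.chrom.sizes"],
                    locus_hits=paths[f"{sp}.hits"],
                    transcript_hits=paths[f"{sp}.transcript_hits"],
                )
                for sp in sim.species
            ],
            outdir=str(outdir),
        )

    def test_end_to_end_and_rerun_identical(self, sim_dir):
        sim, paths, tmp = sim_dir
        r1 = run_pipeline(self.config_for(sim, paths, tmp / "out1"))
        r2 = run_pipeline(self.config_for(sim, paths, tmp / "out2"))
        assert r1.blocks and r1.placements
        files = [
            "anchors.tsv", "blocks.tsv", "blocks.bed", "circos_links.txt",
            "synteny_summary.tsv", "placements.tsv", "unplaced.tsv",
            "consolidated.tsv", "pipeline_log.json",
        ]
        for f in files:
            assert filecmp.cmp(tmp / "out1" / f, tmp / "out2" / f, shallow=False), f

    def test_log_counts_are_consistent(self, sim_dir):
        sim, paths, tmp = sim_dir
        run_pipeline(self.config_for(sim, paths, tmp / "out"))
        log = json.loads((tmp / "out" / "pipeline_log.json").read_text())
        for sp in sim.species:
            st = log["stages"][sp]
            assert st["significant"] <= st["hits"]
            # per-species accounting: anchors + discards = distinct queries
            n_queries = len(
                {h.query_id for h in sim.locus_hits[sp] if h.evalue < 1e-10}
            )
            n_transcript_queries = len(
                {h.query_id for h in sim.transcript_hits[sp] if h.evalue < 1e-10}
            )
            assert (
                st["anchors"] + st["discards"]
                + st["transcript_anchors"] + st["transcript_multi_chromosome"]
                == n_queries + n_transcript_queries
            )
        assert log["overlap"]["disjoint"] is True

    def test_empty_transcript_file_gives_blocks_but_no_placements(
        self, tmp_path
    ):
        sim = simulate(noise_free_config(33, n_transcripts=0))
        paths = sim.write(tmp_path / "data")
        result = run_pipeline(self.config_for(sim, paths, tmp_path / "out"))
        assert result.blocks and not result.placements
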