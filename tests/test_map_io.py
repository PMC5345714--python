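"""Linkage-map I/O, validation, and summary statistics."""

import math

import pytest

from synmap import (
    ChromosomeSet,
    FormatError,
    MapLocus,
    ValidationError,
    build_map,
    map_statistics,
    maps_equal,
    read_chrom_sizes,
    read_linkage_map,
    simulate,
    write_chrom_sizes,
    write_linkage_map,
)
from conftest import noise_free_config

HEADER = "locus_id\tlg\tcm\tclass\tsequence\n"


def write(tmp_path, body, name="map.tsv", header=HEADER):
    path = tmp_path / name
    path.write_text(header + body)
    return path


class TestReadLinkageMap:
    def test_minimal_two_locus_file(self, tmp_path):
        path = write(tmp_path, "A\tlg1\t0.0\tRAD\t\nB\tlg1\t5.0\tSSR\tACGT\n")
        lmap = read_linkage_map(path)
        assert lmap.n_groups == 1 and lmap.n_loci == 2
        assert lmap.groups["lg1"].length == 5.0
        assert lmap.locus_index()["B"].sequence == "ACGT"

    def test_negative_cm_names_the_locus(self, tmp_path):
        path = write(tmp_path, "X\tlg1\t-1.0\tRAD\t\n")
        with pytest.raises(ValidationError, match="X"):
            read_linkage_map(path)

    @pytest.mark.parametrize("missing", ["locus_id", "lg", "cm", "class", "sequence"])
    def test_missing_column_is_named(self, tmp_path, missing):
        cols = [c for c in ("locus_id", "lg", "cm", "class", "sequence") if c != missing]
        header = "\t".join(cols) + "\n"
        row = "\t".join(["A", "lg1", "1.0", "RAD", ""][: len(cols)]) + "\n"
        path = write(tmp_path, row, header=header)
        with pytest.raises(FormatError, match=missing):
            read_linkage_map(path)

    def test_duplicate_locus_id_rejected(self, tmp_path):
        path = write(tmp_path, "A\tlg1\t0.0\tRAD\t\nA\tlg2\t1.0\tRAD\t\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_linkage_map(path)

    def test_unknown_marker_class_rejected(self, tmp_path):
        path = write(tmp_path, "A\tlg1\t0.0\tSNP\t\n")
        with pytest.raises(ValidationError, match="marker class"):
            read_linkage_map(path)


class TestWriteLinkageMap:
    def test_empty_map_writes_header_only(self, tmp_path):
        out = tmp_path / "empty.tsv"
        write_linkage_map(build_map([]), out)
        assert out.read_text().strip() == HEADER.strip()

    def test_two_locus_map_writes_three_lines(self, tmp_path):
        lmap = build_map([MapLocus("A", "lg1", 0.0), MapLocus("B", "lg1", 5.0)])
        out = tmp_path / "two.tsv"
        write_linkage_map(lmap, out)
        assert len(out.read_text().strip().splitlines()) == 3

    def test_round_trip_identity_on_simulated_map(self, tmp_path):
        sim = simulate(noise_free_config(3, n_lgs=2, loci_per_lg=25))
        out = tmp_path / "sim.tsv"
        write_linkage_map(sim.linkage_map, out)
        again = read_linkage_map(out)
        assert maps_equal(sim.linkage_map, again)
        # write o read is idempotent on the file as well
        out2 = tmp_path / "sim2.tsv"
        write_linkage_map(again, out2)
        assert out.read_text() == out2.read_text()


class TestChromSizes:
    def test_parse_and_total(self, tmp_path):
        p = tmp_path / "g.chrom.sizes"
        p.write_text("chr1\t1000\nchr2\t2000\n")
        cs = read_chrom_sizes(p, species="sp")
        assert cs.total_bp == 3000 and cs["chr2"] == 2000

    def test_zero_length_rejected(self, tmp_path):
        p = tmp_path / "bad.chrom.sizes"
        p.write_text("chr1\t0\n")
        with pytest.raises(ValidationError):
            read_chrom_sizes(p, species="sp")

    def test_non_integer_rejected(self, tmp_path):
        p = tmp_path / "bad.chrom.sizes"
        p.write_text("chr1\t12.5\n")
        with pytest.raises(ValidationError):
            read_chrom_sizes(p, species="sp")

    def test_simulated_round_trip(self, tmp_path, small_sim):
        sp = small_sim.species[0]
        p = tmp_path / "sim.chrom.sizes"
        write_chrom_sizes(small_sim.chromosomes[sp], p)
        again = read_chrom_sizes(p, species=sp)
        assert again.sizes == small_sim.chromosomes[sp].sizes


class TestMapStatistics:
    def test_single_group_two_loci(self):
        lmap = build_map([MapLocus("A", "lg1", 0.0), MapLocus("B", "lg1", 10.0)])
        s = map_statistics(lmap)
        assert s.total_length_cM == 10.0
        assert s.mean_marker_interval_cM == 10.0
        assert s.mean_loci_per_group == 2.0

    def test_interval_undefined_for_singleton_groups(self):
        lmap = build_map([MapLocus("A", "lg1", 0.0), MapLocus("B", "lg2", 0.0)])
        s = map_statistics(lmap)
        assert s.mean_marker_interval_cM is None

    def test_empty_map_rejected(self):
        with pytest.raises(ValidationError):
            map_statistics(build_map([]))

    def test_matches_brute_force_on_simulated_map(self):
        sim = simulate(noise_free_config(5, n_lgs=5, loci_per_lg=20))
        s = map_statistics(sim.linkage_map)
        # independent recomputation from the flat locus table
        rows = [
            (l.linkage_group, l.position) for l in sim.linkage_map.iter_loci()
        ]
        groups = {lg for lg, _ in rows}
        total = 0.0
        for lg in groups:
            pos = [p for g, p in rows if g == lg]
            total += max(pos) if len(pos) > 1 else 0.0
        n = len(rows)
        assert s.n_loci == n and s.n_groups == len(groups)
        assert math.isclose(s.total_length_cM, total)
        assert math.isclose(s.mean_lg_size_cM, total / len(groups))
        assert math.isclose(s.mean_marker_interval_cM, total / (n - len(groups)))
        # consistency identity
        assert math.isclose(
            s.mean_marker_interval_cM * (s.n_loci - s.n_groups), s.total_length_cM
        )

    def test_permutation_invariance_of_input_rows(self, tmp_path):
        rows = [
            "B\tlg1\t5.0\tRAD\t",
            "A\tlg1\t0.0\tSSR\t",
            "D\tlg2\t7.5\tRAD\t",
            "C\tlg2\t2.5\tEST-SSR\t",
        ]
        p1 = tmp_path / "fwd.tsv"
        p1.write_text(HEADER + "\n".join(rows) + "\n")
        p2 = tmp_path / "rev.tsv"
        p2.write_text(HEADER + "\n".join(reversed(rows)) + "\n")
        assert map_statistics(read_linkage_map(p1)) == map_statistics(
            read_linkage_map(p2)
        )


def test_chromosome_set_validates_lengths():
    with pytest.raises(ValidationError):
        ChromosomeSet("sp", {"c1": -5})
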