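import numpy as np
import pytest

from quartetscan.genotype_io import (ConfigError, FormatError, MapError,
                                     MISSING, ScaffoldPlacement, Window,
                                     iter_windows, lift_from_chromosome,
                                     lift_to_chromosome, read_population_map,
                                     read_scaffold_map, read_vcf_genotypes,
                                     write_vcf)
from conftest import make_matrix


class TestReadVcf:
    def test_qual_filter_keeps_strictly_above_threshold(self, write_vcf_text):
        path = write_vcf_text([
            "scaf1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\t0/1",
            "scaf1\t200\t.\tC\tG\t20\tPASS\t.\tGT\t0/0\t1/1",
            "scaf1\t300\t.\tG\tA\t45\tPASS\t.\tGT\t1/1\t./.",
        ])
        mat = read_vcf_genotypes(path, min_qual=30)
        assert mat.n_sites == 2
        assert list(mat.pos) == [99, 299]  # converted to 0-based
        assert mat.dosages[0].tolist() == [0, 1]
        assert mat.dosages[1].tolist() == [2, MISSING]

    def test_empty_vcf_yields_empty_matrix(self, write_vcf_text):
        mat = read_vcf_genotypes(write_vcf_text([]))
        assert mat.n_sites == 0
        assert mat.samples == ["s1", "s2"]

    def test_multiallelic_and_indel_records_dropped(self, write_vcf_text):
        path = write_vcf_text([
            "scaf1\t100\t.\tA\tT,G\t50\tPASS\t.\tGT\t0/1\t0/2",
            "scaf1\t200\t.\tA\tT\t50\tPASS\t.\tGT\t0/1\t0/0",
            "scaf1\t300\t.\tAT\tA\t50\tPASS\t.\tGT\t0/1\t0/0",
        ])
        mat = read_vcf_genotypes(path)
        assert mat.n_sites == 1
        assert list(mat.pos) == [199]

    def test_dp_copied_when_present(self, write_vcf_text):
        path = write_vcf_text([
            "scaf1\t100\t.\tA\tT\t50\tPASS\t.\tGT:DP\t0/0:12\t0/1:7",
        ])
        mat = read_vcf_genotypes(path)
        assert mat.depths is not None
        assert mat.depths[0].tolist() == [12, 7]

    def test_unreadable_file_raises(self):
        with pytest.raises(OSError):
            read_vcf_genotypes("/nonexistent/path.vcf")


class TestPopulationMap:
    def _write(self, tmp_path, rows):
        p = tmp_path / "pops.tsv"
        p.write_text("".join(f"{s}\t{t}\t{r}\n" for s, t, r in rows))
        return str(p)

    def test_roles_counted(self, tmp_path):
        rows = ([(f"a{i}", "taxA", "P1") for i in range(4)]
                + [(f"b{i}", "taxB", "P2") for i in range(4)]
                + [(f"c{i}", "taxC", "P3") for i in range(4)]
                + [("o0", "taxO", "O")]
                + [(f"x{i}", "taxX", "ignore") for i in range(4)])
        q = read_population_map(self._write(tmp_path, rows))
        assert tuple(map(len, (q.p1, q.p2, q.p3, q.o))) == (4, 4, 4, 1)
        assert q.labels["P2"] == "taxB"

    def test_missing_roles_is_config_error(self, tmp_path):
        path = self._write(tmp_path, [("a", "t", "P1"), ("b", "t", "P1")])
        with pytest.raises(ConfigError):
            read_population_map(path)

    def test_duplicate_sample_is_format_error(self, tmp_path):
        path = self._write(tmp_path, [("a", "t", "P1"), ("a", "t", "P2")])
        with pytest.raises(FormatError):
            read_population_map(path)


class TestScaffoldLift:
    def test_forward_offset(self):
        mat = make_matrix([100], [[0, 1]], chrom="scafA")
        smap = {"scafA": ScaffoldPlacement("chr1", 5_000, "+", 1_000)}
        lifted = lift_to_chromosome(mat, smap)
        assert lifted.pos[0] == 5_100
        assert lifted.chroms[0] == "chr1"

    def test_reverse_orientation_flips(self):
        mat = make_matrix([100], [[0, 1]], chrom="scafA")
        smap = {"scafA": ScaffoldPlacement("chr1", 0, "-", 1_000)}
        lifted = lift_to_chromosome(mat, smap)
        assert lifted.pos[0] == 899

    def test_unplaced_scaffold_retained_and_flagged(self):
        mat = make_matrix([100], [[0, 1]], chrom="scafX")
        lifted = lift_to_chromosome(mat, {})
        assert lifted.chroms[0] == "scafX"
        assert lifted.pos[0] == 100
        assert lifted.unplaced[0]

    def test_overlapping_placements_rejected(self):
        smap = {"a": ScaffoldPlacement("chr1", 0, "+", 1_000),
                "b": ScaffoldPlacement("chr1", 500, "+", 1_000)}
        mat = make_matrix([10], [[0, 0]], chrom="a")
        with pytest.raises(MapError):
            lift_to_chromosome(mat, smap)

    def test_lift_preserves_site_count_and_inverts(self):
        rng = np.random.default_rng(0)
        pos = np.sort(rng.choice(900, size=30, replace=False))
        chroms = np.where(pos < 450, "scafA", "scafB").astype(object)
        pos = np.where(pos < 450, pos, pos - 450)
        # re-sort within scaffold
        order = np.lexsort((pos, chroms.astype(str)))
        mat = make_matrix(pos[order], rng.integers(0, 3, size=(30, 2)),
                          chrom=chroms[order])
        smap = {"scafA": ScaffoldPlacement("chr1", 0, "+", 450),
                "scafB": ScaffoldPlacement("chr1", 450, "-", 450)}
        lifted = lift_to_chromosome(mat, smap)
        assert lifted.n_sites == mat.n_sites
        back = lift_from_chromosome(lifted, smap)
        assert sorted(zip(back.chroms, back.pos)) == sorted(zip(mat.chroms,
                                                                mat.pos))

    def test_scaffold_map_roundtrip(self, tmp_path):
        p = tmp_path / "smap.tsv"
        p.write_text("scafA\tchr1\t0\t+\t450\nscafB\tchr1\t450\t-\t450\n")
        smap = read_scaffold_map(str(p))
        assert smap["scafB"].strand == "-"
        assert smap["scafB"].length == 450


class TestWindows:
    def test_tiling_with_terminal_partial(self):
        mat = make_matrix([100, 11_999], [[0, 0], [1, 1]])
        wins = list(iter_windows(mat, 5_000, lengths={"chr1": 12_000}))
        assert [(w.start, w.end, w.partial) for w in wins] == [
            (0, 5_000, False), (5_000, 10_000, False), (10_000, 12_000, True)]

    def test_short_chromosome_single_partial(self):
        mat = make_matrix([10], [[0, 0]])
        wins = list(iter_windows(mat, 5_000, lengths={"chr1": 3_000}))
        assert len(wins) == 1 and wins[0].partial

    def test_exact_tiling_no_partial(self):
        mat = make_matrix([10], [[0, 0]])
        wins = list(iter_windows(mat, 50_000, lengths={"chr1": 100_000}))
        assert len(wins) == 2 and not any(w.partial for w in wins)

    def test_every_site_covered_exactly_once(self):
        rng = np.random.default_rng(1)
        pos = np.sort(rng.choice(23_000, size=200, replace=False))
        mat = make_matrix(pos, rng.integers(0, 3, size=(200, 3)))
        covered = []
        for w in iter_windows(mat, 5_000):
            covered += list(mat.sites_in(w.chrom, w.start, w.end))
        assert sorted(covered) == list(range(200))
        assert len(set(covered)) == 200

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            Window("chr1", 100, 100, 5_000)


class TestVcfRoundTrip:
    def test_write_read_reproduces_dosages_and_positions(self, tmp_path):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(10_000, size=50, replace=False))
        dosages = rng.integers(-1, 3, size=(50, 5))
        depths = rng.integers(0, 60, size=(50, 5))
        mat = make_matrix(pos, dosages, depths=depths)
        out = tmp_path / "rt.vcf"
        write_vcf(mat, str(out))
        back = read_vcf_genotypes(str(out), min_qual=0)
        np.testing.assert_array_equal(back.pos, mat.pos)
        np.testing.assert_array_equal(back.dosages, mat.dosages)
        np.testing.assert_array_equal(back.depths, mat.depths)
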