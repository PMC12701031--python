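"""Genetic-map data model, I/O, rescaling, windowing, and consensus maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_map
from recmap.genmap import (
    GeneticMap,
    read_map,
    rescale_map,
    to_segments,
    weighted_average_maps,
    window_rates,
    write_map,
)


class TestGeneticMap:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError, match="not strictly increasing"):
            GeneticMap("chr1", [1, 1], [0.0, 1.0])
        with pytest.raises(ValueError, match="decrease"):
            GeneticMap("chr1", [1, 100], [1.0, 0.0])

    def test_rates_derived_from_cm(self, three_marker_map):
        assert three_marker_map.rates() == pytest.approx([1.0, 2.0])

    def test_cm_interpolation_clamped(self, three_marker_map):
        assert three_marker_map.cm_at(500_000) == pytest.approx(0.5)
        assert three_marker_map.cm_at(-10) == 0.0
        assert three_marker_map.cm_at(9_999_999) == 3.0


class TestSegments:
    def test_single_segment_rate(self):
        m = GeneticMap("chr1", [1, 1_000_001], [0.0, 1.0])
        (seg,) = to_segments(m)
        assert seg.rate == pytest.approx(1.0)
        assert (seg.start, seg.end) == (0, 1_000_000)

    def test_zero_rate_segment(self):
        m = GeneticMap("chr1", [1, 1001], [0.5, 0.5])
        assert to_segments(m)[0].rate == 0.0

    def test_conservation_of_genetic_length(self):
        rng = np.random.default_rng(5)
        m = random_map(rng, n_markers=5)
        total = sum(s.cm for s in to_segments(m))
        assert total == pytest.approx(m.total_cm, rel=1e-9)

    def test_too_few_markers(self):
        assert to_segments(GeneticMap("chr1", [5], [0.0])) == []


class TestRescale:
    def test_identity(self, three_marker_map):
        out = rescale_map(three_marker_map, 3.0)
        np.testing.assert_allclose(out.genetic_positions,
                                   three_marker_map.genetic_positions)

    def test_doubling_doubles_rates(self, three_marker_map):
        out = rescale_map(three_marker_map, 6.0)
        np.testing.assert_allclose(out.rates(), 2 * three_marker_map.rates())
        assert out.total_cm == pytest.approx(6.0)

    def test_target_zero(self, three_marker_map):
        out = rescale_map(three_marker_map, 0.0)
        assert np.all(out.genetic_positions == 0)

    def test_zero_length_map_rejected(self):
        flat = GeneticMap("chr1", [1, 100], [0.0, 0.0])
        with pytest.raises(ValueError):
            rescale_map(flat, 5.0)

    @given(a=st.floats(0.1, 100), b=st.floats(0.1, 100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rescaling_is_linear(self, a, b):
        m = GeneticMap("chr1", [1, 500_001, 2_000_001], [0.0, 2.0, 3.0])
        twice = rescale_map(rescale_map(m, a), b)
        once = rescale_map(m, b)
        np.testing.assert_allclose(twice.genetic_positions, once.genetic_positions)


class TestWeightedAverage:
    def test_idempotence_on_identical_maps(self, three_marker_map):
        out = weighted_average_maps([three_marker_map] * 4, [48, 36, 34, 26])
        np.testing.assert_allclose(out.genetic_positions,
                                   three_marker_map.genetic_positions)

    def test_two_uniform_maps_equal_weights(self):
        pos = [1, 1_000_001, 2_000_001]
        m1 = GeneticMap("chr1", pos, [0.0, 1.0, 2.0])   # 1 cM/Mb
        m3 = GeneticMap("chr1", pos, [0.0, 3.0, 6.0])   # 3 cM/Mb
        out = weighted_average_maps([m1, m3], [1, 1])
        np.testing.assert_allclose(out.rates(), [2.0, 2.0])

    def test_weights_change_result(self):
        pos = [1, 1_000_001, 2_000_001]
        m1 = GeneticMap("chr1", pos, [0.0, 1.0, 2.0])
        m3 = GeneticMap("chr1", pos, [0.0, 3.0, 6.0])
        out = weighted_average_maps([m1, m3], [3, 1])
        np.testing.assert_allclose(out.rates(), [1.5, 1.5])  # (3*1 + 1*3)/4

    def test_restricts_to_common_interval(self):
        a = GeneticMap("chr1", [1, 2_000_001], [0.0, 2.0])
        b = GeneticMap("chr1", [1_000_001, 3_000_001], [0.0, 2.0])
        out = weighted_average_maps([a, b], [1, 1])
        assert out.positions[0] == 1_000_001
        assert out.positions[-1] == 2_000_001

    def test_disjoint_coverage_rejected(self):
        a = GeneticMap("chr1", [1, 1_000_001], [0.0, 1.0])
        b = GeneticMap("chr1", [2_000_001, 3_000_001], [0.0, 1.0])
        with pytest.raises(ValueError, match="common"):
            weighted_average_maps([a, b], [1, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_segment_brute_force(self, seed):
        """Oracle: on each union segment the consensus rate is sum(w r)/sum(w)
        with r taken from each input's piecewise-constant profile."""
        rng = np.random.default_rng(seed)
        maps = []
        for _ in range(3):
            inner = rng.integers(2, 4_999_999, size=rng.integers(1, 4))
            pos = np.unique(np.concatenate([[1, 5_000_000], inner]))
            rates = rng.gamma(0.5, 2.0, size=len(pos) - 1)
            cm = np.concatenate([[0.0], np.cumsum(rates * np.diff(pos) / 1e6)])
            maps.append(GeneticMap("chr1", pos, cm))
        w = rng.integers(1, 50, size=3).astype(float)
        out = weighted_average_maps(maps, w)
        for left, right, rate in zip(out.positions[:-1], out.positions[1:],
                                     out.rates()):
            mid = (left + right) / 2
            expected = 0.0
            for m, wi in zip(maps, w):
                i = np.searchsorted(m.positions, mid) - 1
                expected += wi * m.rates()[i]
            expected /= w.sum()
            assert rate == pytest.approx(expected, rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_total_is_weighted_mean_over_common_interval(self, seed):
        rng = np.random.default_rng(100 + seed)
        maps = [random_map(rng, n_markers=5) for _ in range(2)]
        w = [2.0, 5.0]
        out = weighted_average_maps(maps, w)
        lo, hi = out.positions[0] - 1, out.positions[-1] - 1
        expected = sum(wi * (m.cm_at(hi) - m.cm_at(lo)) for m, wi in zip(maps, w))
        expected /= sum(w)
        assert out.total_cm == pytest.approx(expected, rel=1e-9)


class TestWindowRates:
    def test_uniform_map_uniform_windows(self, uniform_map):
        table = window_rates(uniform_map, 1_000_000)
        assert np.allclose(table["rate"].dropna(), 1.0)

    def test_weighted_mean_across_rate_change(self):
        # 0 cM/Mb on [0, 1 Mb), 2 cM/Mb on [1 Mb, 2 Mb); window straddles both
        m = GeneticMap("chr1", [1, 1_000_001, 2_000_001], [0.0, 0.0, 2.0])
        table = window_rates(m, 1_000_000, centers_bp=[1_000_000])
        assert table["rate"].iloc[0] == pytest.approx(1.0)

    def test_uncovered_window_is_missing_not_zero(self, three_marker_map):
        table = window_rates(three_marker_map, 1_000_000, end_bp=5_000_000)
        assert np.isnan(table["rate"].iloc[-1])
        assert not np.isnan(table["rate"].iloc[0])

    def test_whole_chromosome_window_reproduces_mean(self, three_marker_map):
        span = three_marker_map.span_bp
        table = window_rates(three_marker_map, span, centers_bp=[span // 2])
        assert table["rate"].iloc[0] == pytest.approx(
            three_marker_map.total_cm / (span / 1e6))


class TestIO:
    def test_hapmap_cm_column_derives_rates(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)\n"
            "chr1\t1\t0\t0\nchr1\t1000001\t0\t1\nchr1\t2000001\t0\t3\n"
        )
        maps = read_map(str(path))
        assert maps["chr1"].rates() == pytest.approx([1.0, 2.0])

    def test_hapmap_rate_column_reconstructs_cm(self, tmp_path):
        path = tmp_path / "map.tsv"
        path.write_text(
            "Chromosome\tPosition(bp)\tRate(cM/Mb)\n"
            "chr1\t1\t1.0\nchr1\t1000001\t2.0\nchr1\t2000001\t0.0\n"
        )
        maps = read_map(str(path))
        np.testing.assert_allclose(maps["chr1"].genetic_positions, [0.0, 1.0, 3.0])

    def test_empty_file_empty_collection(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert read_map(str(path)) == {}

    def test_non_monotone_position_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "Chromosome\tPosition(bp)\tMap(cM)\n"
            "chr1\t100\t0\nchr1\t50\t1\n"
        )
        with pytest.raises(ValueError, match="bad.tsv:3"):
            read_map(str(path))

    def test_negative_rate_rejected(self, tmp_path):
        path = tmp_path / "neg.tsv"
        path.write_text("Chromosome\tPosition(bp)\tRate(cM/Mb)\nchr1\t1\t-1\n")
        with pytest.raises(ValueError, match="negative rate"):
            read_map(str(path))

    @pytest.mark.parametrize("dialect", ["hapmap_tsv", "plink_map"])
    def test_round_trip_exact(self, tmp_path, dialect, three_marker_map):
        path = tmp_path / "out.map"
        write_map({"chr1": three_marker_map}, str(path), dialect=dialect)
        back = read_map(str(path), dialect=dialect)
        np.testing.assert_array_equal(back["chr1"].positions,
                                      three_marker_map.positions)
        np.testing.assert_array_equal(back["chr1"].genetic_positions,
                                      three_marker_map.genetic_positions)

    def test_hapmap_export_rate_column_matches_segments(self, tmp_path,
                                                        three_marker_map):
        path = tmp_path / "out.tsv"
        write_map(three_marker_map, str(path))
        rates = [float(line.split("\t")[2])
                 for line in path.read_text().splitlines()[1:]]
        assert rates[:-1] == pytest.approx(list(three_marker_map.rates()))
        assert rates[-1] == 0.0
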