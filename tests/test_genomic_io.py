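import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobindscan.genomic_io import (BlacklistSet, CoverageTrack, GenomeLayout, ParseError,
                                   Peak, interval_coverage_sum, read_narrowpeak,
                                   subtract_blacklist, write_narrowpeak)
from conftest import make_random_peaks, make_random_track, per_base_sum


class TestNarrowPeak:
    def test_summit_from_offset_column(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t500\tp1\t0\t.\t75.0\t9.1\t-1\t150\n")
        (p,) = read_narrowpeak(path)
        assert (p.chrom, p.start, p.end, p.summit) == ("chr1", 100, 500, 250)
        assert (p.pileup, p.fold_enrichment) == (75.0, 9.1)

    def test_negative_offset_falls_back_to_midpoint(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t500\tp1\t0\t.\t75.0\t9.1\t-1\t-1\n")
        (p,) = read_narrowpeak(path)
        assert p.summit == 300

    def test_round_trip_random_peaks(self, rng, tmp_path):
        peaks = make_random_peaks(rng, 100)
        path = tmp_path / "rt.narrowPeak"
        write_narrowpeak(peaks, path)
        assert read_narrowpeak(path) == peaks

    def test_gzip_transparent(self, rng, tmp_path):
        peaks = make_random_peaks(rng, 10)
        path = tmp_path / "rt.narrowPeak.gz"
        write_narrowpeak(peaks, path)
        with gzip.open(path, "rt") as fh:
            assert len(fh.readlines()) == 10
        assert read_narrowpeak(path) == peaks

    @pytest.mark.parametrize(
        "line",
        [
            "chr1\t100\t500\tp1\t0\t.\t75.0\n",          # too few columns
            "chr1\t100\t500\tp1\t0\t.\tx\t9.1\t-1\t150\n",  # non-numeric
            "chr1\t100\t500\tp1\t0\t.\t75.0\t9.1\t-1\t400\n",  # offset >= length
        ],
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t0\t200\tok\t0\t.\t60\t6\t-1\t100\n" + line)
        with pytest.raises(ParseError, match="line 2"):
            read_narrowpeak(path)


class TestPeakValidation:
    def test_summit_must_lie_inside_interval(self):
        with pytest.raises(ValueError):
            Peak("chr1", 100, 200, 250, 10.0, 5.0)
        with pytest.raises(ValueError):
            Peak("chr1", 200, 100, 150, 10.0, 5.0)


class TestBlacklist:
    def test_empty_blacklist_is_identity(self, rng):
        peaks = make_random_peaks(rng, 20)
        assert subtract_blacklist(peaks, BlacklistSet()) == peaks

    def test_summit_containment_removes_peak(self):
        p = Peak("chr1", 900, 1100, 1000, 10.0, 5.0, "p")
        bl = BlacklistSet([("chr1", 900, 1100)])
        assert subtract_blacklist([p], bl) == []
        # summit just outside the interval is kept under summit mode
        q = Peak("chr1", 1050, 1300, 1100, 10.0, 5.0, "q")
        assert subtract_blacklist([q], bl) == [q]
        assert subtract_blacklist([q], bl, mode="overlap") == []

    def test_matches_brute_force_containment(self, rng):
        peaks = make_random_peaks(rng, 200)
        intervals = []
        for _ in range(20):
            s = int(rng.integers(0, 990_000))
            intervals.append(("chr1", s, s + int(rng.integers(100, 10_000))))
        bl = BlacklistSet(intervals)
        expected = [
            p for p in peaks
            if not any(c == p.chrom and s <= p.summit < e for c, s, e in intervals)
        ]
        result = subtract_blacklist(peaks, bl)
        assert result == expected
        # idempotent and never grows
        assert subtract_blacklist(result, bl) == result
        assert len(result) <= len(peaks)


class TestCoverageTrack:
    def test_constant_coverage_window(self):
        track = CoverageTrack({"chr1": ([0], [10_000], [1.0])})
        assert track.interval_sum("chr1", 400, 1000) == 600.0

    def test_query_in_zero_gap(self):
        track = CoverageTrack({"chr1": ([0, 5000], [1000, 6000], [2.0, 3.0])})
        assert track.interval_sum("chr1", 2000, 3000) == 0.0

    def test_random_track_matches_per_base_oracle(self, rng):
        track = make_random_track(rng, n_runs=50, span=20_000)
        for _ in range(100):
            a = int(rng.integers(0, 19_000))
            b = a + int(rng.integers(1, 1000))
            assert track.interval_sum("chr1", a, b) == pytest.approx(
                per_base_sum(track, "chr1", a, b), abs=1e-9)

    def test_off_chromosome_query_is_clipped(self):
        layout = GenomeLayout({"chr1": 1000})
        track = CoverageTrack({"chr1": ([0], [1000], [1.0])}, layout=layout)
        assert track.interval_sum("chr1", -500, 100) == 100.0
        assert track.interval_sum("chr1", 900, 5000) == 100.0

    @settings(deadline=None, max_examples=50)
    @given(a=st.integers(0, 9_000), gap=st.integers(1, 500), length=st.integers(1, 500))
    def test_additive_over_partitions(self, a, gap, length):
        track = CoverageTrack({"chr1": ([0, 4000], [3000, 9999], [1.5, 0.25])})
        b, c = a + gap, a + gap + length
        left = track.interval_sum("chr1", a, b)
        right = track.interval_sum("chr1", b, c)
        assert left + right == pytest.approx(track.interval_sum("chr1", a, c), abs=1e-9)

    def test_reencoding_preserves_sums(self, rng):
        track = make_random_track(rng, n_runs=30, span=20_000)
        split = track.reencoded(pieces=3)
        for _ in range(50):
            a = int(rng.integers(0, 19_000))
            b = a + int(rng.integers(1, 900))
            assert split.interval_sum("chr1", a, b) == pytest.approx(
                track.interval_sum("chr1", a, b), abs=1e-9)

    def test_bedgraph_round_trip(self, rng, tmp_path):
        track = make_random_track(rng, n_runs=25, span=50_000)
        path = tmp_path / "t.bedGraph"
        track.to_bedgraph(path)
        back = CoverageTrack.from_bedgraph(path)
        s, e, v, _ = track._runs["chr1"]
        s2, e2, v2, _ = back._runs["chr1"]
        assert np.array_equal(s, s2) and np.array_equal(e, e2)
        assert np.allclose(v, v2)

    def test_rejects_overlapping_runs(self):
        with pytest.raises(ValueError):
            CoverageTrack({"chr1": ([0, 500], [1000, 1500], [1.0, 1.0])})

    def test_module_level_wrapper(self):
        track = CoverageTrack({"chr1": ([0], [100], [2.0])})
        assert interval_coverage_sum(track, "chr1", 0, 50) == 100.0
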