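"""Peak model: parsing, merging, top-N, windows, overlap, filtering."""

import numpy as np
import pytest

from motifbench.errors import (
    MalformedIntervalError,
    UndefinedOverlapError,
    UnknownChromosomeError,
)
from motifbench.ere_profile import RepeatAnnotation
from motifbench.peaks import (
    Peak,
    PeakSet,
    extract_window_sequences,
    filter_non_ere,
    merge_peaks,
    overlap_percentage,
    read_peaks,
    summit_window,
    top_n,
    write_peaks,
)


def peak(start, end, score=1.0, summit=None, chrom="chr1"):
    return Peak(chrom, start, end, (start + end) // 2 if summit is None else summit, score)


def pset(*peaks, protein="P", dataset="d"):
    return PeakSet(protein=protein, dataset=dataset, peaks=tuple(peaks))


class TestIO:
    def test_parse_line(self):
        ps = read_peaks("chr1\t100\t200\tp1\t9.5\t50\n")
        p = ps.peaks[0]
        assert (p.chrom, p.start, p.end, p.summit, p.score) == ("chr1", 100, 200, 150, 9.5)

    def test_midpoint_sentinel(self):
        ps = read_peaks("chr1\t100\t200\tp1\t1\t-1\n")
        assert ps.peaks[0].summit == 150

    def test_inverted_interval_reports_line(self):
        with pytest.raises(MalformedIntervalError, match="line 1"):
            read_peaks("chr1\t200\t100\tp1\t1\t0\n")

    def test_non_integer_coordinate(self):
        with pytest.raises(MalformedIntervalError):
            read_peaks("chr1\tx\t100\tp1\t1\t0\n")

    def test_round_trip(self):
        ps = pset(peak(100, 200, 9.5, summit=150), peak(300, 400, 2.0))
        back = read_peaks(write_peaks(ps), protein="P", dataset="d")
        assert back.peaks == ps.peaks

    def test_summit_must_lie_inside(self):
        with pytest.raises(MalformedIntervalError):
            Peak("chr1", 100, 200, 300, 1.0)


class TestMerge:
    def test_gap_at_most_max_gap_merges(self):
        merged = merge_peaks(pset(peak(100, 200), peak(240, 300)))
        assert len(merged) == 1
        assert (merged.peaks[0].start, merged.peaks[0].end) == (100, 300)

    def test_gap_beyond_max_gap_kept_separate(self):
        merged = merge_peaks(pset(peak(100, 200), peak(251, 300)))
        assert len(merged) == 2

    def test_merged_peak_inherits_highest_scoring_member(self):
        merged = merge_peaks(
            pset(peak(100, 200, 5.0), peak(150, 260, 9.0, summit=210))
        )
        p = merged.peaks[0]
        assert (p.start, p.end, p.score, p.summit) == (100, 260, 9.0, 210)

    def test_idempotent(self):
        gen = np.random.default_rng(4)
        peaks = []
        for _ in range(100):
            s = int(gen.integers(0, 100_000))
            peaks.append(peak(s, s + int(gen.integers(10, 400)), float(gen.random())))
        once = merge_peaks(pset(*peaks))
        twice = merge_peaks(once)
        assert once.peaks == twice.peaks
        gaps = [
            b.start - a.end
            for a, b in zip(once.peaks, once.peaks[1:])
            if a.chrom == b.chrom
        ]
        assert all(g > 50 for g in gaps)


class TestTopN:
    def test_fewer_peaks_than_n_keeps_all(self):
        ps = pset(peak(0, 10), peak(20, 30), peak(40, 50))
        assert len(top_n(ps, 500)) == 3

    def test_keeps_highest_scores(self):
        peaks = [peak(i * 100, i * 100 + 50, score=float(i)) for i in range(1000)]
        best = top_n(pset(*peaks), 500)
        assert len(best) == 500
        assert min(p.score for p in best.peaks) == 500.0

    def test_scores_non_increasing_and_tie_broken_by_position(self):
        ps = pset(peak(500, 510, 1.0), peak(100, 110, 1.0), peak(0, 10, 2.0))
        best = top_n(ps, 2)
        scores = [p.score for p in best.peaks]
        assert scores == sorted(scores, reverse=True)
        assert best.peaks[1].start == 100  # earlier coordinate wins the tie


class TestWindows:
    def test_default_window_is_501_bases(self):
        start, end = summit_window(peak(900, 1100, summit=1000), 250, 10_000)
        assert (start, end) == (750, 1251)
        assert end - start == 501

    def test_clipped_at_chromosome_start(self):
        start, end = summit_window(peak(50, 150, summit=100), 250, 10_000)
        assert (start, end) == (0, 351)

    def test_zero_flank(self):
        assert summit_window(peak(90, 110, summit=100), 0, 1000) == (100, 101)

    def test_extract_matches_genome_slice(self):
        gen = np.random.default_rng(1)
        chrom = "".join(gen.choice(list("ACGT")) for _ in range(10_000))
        genome = {"chr1": chrom}
        ps = pset(peak(4_000, 4_200, summit=4_100))
        (seq,) = extract_window_sequences(ps, genome)
        assert seq == chrom[3850:4351] and len(seq) == 501

    def test_extract_clips_near_start(self):
        genome = {"chr1": "ACGT" * 300}
        ps = pset(peak(50, 150, summit=100))
        (seq,) = extract_window_sequences(ps, genome)
        assert len(seq) == 351

    def test_unknown_chromosome_named(self):
        ps = pset(peak(0, 10, chrom="chrZ"))
        with pytest.raises(UnknownChromosomeError, match="chrZ"):
            extract_window_sequences(ps, {"chr1": "ACGT" * 100})


class TestOverlap:
    def test_self_overlap_is_100(self):
        ps = pset(peak(1000, 1200), peak(5000, 5100))
        assert overlap_percentage(ps, ps) == 100.0

    def test_disjoint_chromosomes_give_zero(self):
        a = pset(peak(1000, 1200, chrom="chr1"))
        b = pset(peak(1000, 1200, chrom="chr2"))
        assert overlap_percentage(a, b) == 0.0

    @pytest.mark.parametrize("distance,expected", [(400, 100.0), (600, 0.0)])
    def test_summit_distance_boundary(self, distance, expected):
        a = pset(peak(1000, 1100, summit=1050))
        b = pset(peak(1000 + distance, 1100 + distance, summit=1050 + distance))
        assert overlap_percentage(a, b) == expected

    def test_directional(self):
        a = pset(peak(1000, 1100, summit=1050), peak(9000, 9100, summit=9050))
        b = pset(peak(1020, 1120, summit=1070))
        assert overlap_percentage(a, b) == 50.0
        assert overlap_percentage(b, a) == 100.0

    def test_strict_summit_in_window_rule(self):
        a = pset(peak(1000, 1100, summit=1050))
        b = pset(peak(1400, 1500, summit=1450))  # distance 400: <=500, >250
        assert overlap_percentage(a, b) == 100.0
        assert overlap_percentage(a, b, summit_in_window=True) == 0.0

    def test_empty_set_rejected(self):
        ps = pset(peak(0, 10))
        with pytest.raises(UndefinedOverlapError):
            overlap_percentage(ps, PeakSet(protein="P", dataset="e", peaks=()))

    def test_shifted_copy_decays_to_zero(self):
        peaks = [peak(i * 5000, i * 5000 + 100) for i in range(1, 10)]
        a = pset(*peaks)
        shifted = pset(*[
            Peak(p.chrom, p.start + 600, p.end + 600, p.summit + 600, p.score)
            for p in peaks
        ])
        assert overlap_percentage(a, shifted) == 0.0


class TestFilterNonEre:
    REPEATS = RepeatAnnotation(
        intervals=(("chr1", 2000, 2600, "L1"), ("chr1", 8000, 8300, "Alu"))
    )

    def test_window_inside_repeat_removed(self):
        ps = pset(peak(2200, 2300, summit=2250))
        assert len(filter_non_ere(ps, self.REPEATS)) == 0

    def test_single_base_overlap_removed(self):
        # summit 2849 -> window [2599, 3100): exactly one base of L1 [2000, 2600)
        touching = pset(peak(2840, 2860, summit=2849))
        clear = pset(peak(2840, 2860, summit=2851))  # window starts at 2601
        assert len(filter_non_ere(touching, self.REPEATS)) == 0
        assert len(filter_non_ere(clear, self.REPEATS)) == 1

    def test_empty_annotation_keeps_everything(self):
        ps = pset(peak(2200, 2300), peak(8100, 8200))
        empty = RepeatAnnotation(intervals=())
        assert filter_non_ere(ps, empty).peaks == ps.peaks

    def test_result_windows_disjoint_from_repeats_brute_force(self):
        gen = np.random.default_rng(9)
        peaks = [
            peak(int(s), int(s) + 100)
            for s in gen.integers(300, 20_000, size=200)
        ]
        kept = filter_non_ere(pset(*peaks), self.REPEATS)
        for p in kept.peaks:
            w0, w1 = p.summit - 250, p.summit + 251
            for _c, r0, r1, _n in self.REPEATS.intervals:
                assert w1 <= r0 or w0 >= r1
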