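"""Tag extension, deduplication, binning, RPM, anchor profiles, FPKM."""

import numpy as np
import pytest

from enhancerkit.core import GenomeLayout, Interval, StrandedTag
from enhancerkit.pipeline import prepare_tags
from enhancerkit.signal import (
    LibraryStats,
    Tags,
    anchor_profile,
    bin_counts,
    deduplicate_tags,
    extend_tags,
    read_tagalign,
    region_fpkm,
    rpm_normalize,
    write_tagalign,
)

LAYOUT = GenomeLayout.from_pairs([("chr1", 1_000_000), ("chr2", 500_000)])


def tag(chrom, start, end, strand):
    return StrandedTag(Interval(chrom, start, end), strand)


class TestExtendTags:
    def test_plus_strand_grows_at_end(self):
        (out,) = extend_tags([tag("chr1", 1000, 1036, "+")], 100, LAYOUT).to_records()
        assert (out.interval.start, out.interval.end) == (1000, 1136)

    def test_minus_strand_grows_at_start(self):
        (out,) = extend_tags([tag("chr1", 1000, 1036, "-")], 100, LAYOUT).to_records()
        assert (out.interval.start, out.interval.end) == (900, 1036)

    def test_clamped_at_chromosome_start(self):
        (out,) = extend_tags([tag("chr1", 30, 66, "-")], 100, LAYOUT).to_records()
        assert (out.interval.start, out.interval.end) == (0, 66)

    def test_clamped_at_chromosome_end(self):
        (out,) = extend_tags(
            [tag("chr2", 499_980, 499_999, "+")], 100, LAYOUT
        ).to_records()
        assert out.interval.end == 500_000


class TestDeduplicate:
    def test_exact_duplicates_collapse(self):
        tags = [tag("chr1", 100, 136, "+")] * 3
        kept, rate = deduplicate_tags(tags)
        assert len(kept) == 1 and rate == pytest.approx(2 / 3)

    def test_strand_is_part_of_the_key(self):
        tags = [tag("chr1", 100, 136, "+"), tag("chr1", 100, 136, "-")]
        kept, rate = deduplicate_tags(tags)
        assert len(kept) == 2 and rate == 0.0

    def test_empty_input(self):
        kept, rate = deduplicate_tags([])
        assert len(kept) == 0 and rate == 0.0

    def test_pipeline_deduplicates_before_extending(self):
        # two distinct minus tags that extension would clamp onto the same
        # start: dedup-then-extend keeps both, extend-then-dedup would not
        tags = Tags.from_records([tag("chr1", 30, 66, "-"), tag("chr1", 20, 56, "-")])
        prepared, stats = prepare_tags(tags, LAYOUT, 100, dedup_threshold=-1.0)
        assert len(prepared) == 2
        ext_first, _ = deduplicate_tags(extend_tags(tags, 100, LAYOUT))
        assert len(ext_first) == 1


class TestBinning:
    def test_midpoint_counting_hits_one_bin(self):
        track = bin_counts([tag("chr1", 1000, 1136, "+")], LAYOUT, 100, "midpoint")
        vec = track.vector("chr1")
        assert vec[10] == 1 and vec.sum() == 1  # midpoint 1068 -> bin 10

    def test_overlap_counting_hits_every_bin_touched(self):
        track = bin_counts([tag("chr1", 1000, 1136, "+")], LAYOUT, 100, "overlap")
        vec = track.vector("chr1")
        assert vec[10] == 1 and vec[11] == 1 and vec.sum() == 2

    def test_no_tags_gives_all_zero_track(self):
        track = bin_counts([], LAYOUT, 100)
        assert track.vector("chr1").sum() == 0

    def test_midpoint_counting_conserves_tag_total(self):
        rng = np.random.default_rng(2)
        tags = [
            tag("chr1", int(s), int(s) + 36, "+" if rng.random() < 0.5 else "-")
            for s in rng.integers(0, 999_000, 500)
        ]
        track = bin_counts(tags, LAYOUT, 100, "midpoint")
        assert track.total() == 500


class TestRpm:
    def test_unit_library(self):
        track = bin_counts([tag("chr1", 450, 550, "+")] * 5, LAYOUT, 100)
        rpm = rpm_normalize(track, LibraryStats(1_000_000))
        assert rpm.vector("chr1")[5] == pytest.approx(5.0)

    def test_ten_million_library(self):
        track = bin_counts([tag("chr1", 450, 550, "+")] * 20, LAYOUT, 100)
        rpm = rpm_normalize(track, LibraryStats(10_000_000))
        assert rpm.vector("chr1")[5] == pytest.approx(2.0)

    def test_linearity_in_counts(self):
        rng = np.random.default_rng(3)
        tags = [tag("chr1", int(s), int(s) + 36, "+") for s in rng.integers(0, 999_000, 200)]
        stats = LibraryStats(2_000_000)
        one = rpm_normalize(bin_counts(tags, LAYOUT, 100), stats)
        three = rpm_normalize(bin_counts(tags * 3, LAYOUT, 100), stats)
        np.testing.assert_allclose(three.vector("chr1"), 3 * one.vector("chr1"))


class TestAnchorProfile:
    def _uniform_track(self, value=2.5):
        data = {"chr1": np.full(10_000, value)}
        from enhancerkit.signal import CoverageTrack

        return CoverageTrack(LAYOUT, 100, data, unit="rpm")

    def test_bin_count_is_twice_half_width_over_bin_size(self):
        prof = anchor_profile(self._uniform_track(), [("chr1", 500_000, "+")], 5000)
        assert len(prof.bins) == 100

    def test_uniform_track_gives_constant_profile(self):
        prof = anchor_profile(self._uniform_track(2.5), [("chr1", 500_000, "+")], 5000)
        np.testing.assert_allclose(prof.bins, 2.5)

    def test_identical_anchors_average_to_single_anchor_profile(self):
        track = self._uniform_track()
        track.data["chr1"][4990:5010] = 9.0
        single = anchor_profile(track, [("chr1", 500_000, "+")], 5000)
        many = anchor_profile(track, [("chr1", 500_000, "+")] * 4, 5000)
        np.testing.assert_allclose(single.bins, many.bins)

    def test_minus_strand_anchor_reverses_the_window(self):
        track = self._uniform_track(0.0)
        track.data["chr1"][5010] = 7.0  # +1000..1100 bp downstream of anchor
        plus = anchor_profile(track, [("chr1", 500_000, "+")], 5000)
        minus = anchor_profile(track, [("chr1", 500_000, "-")], 5000)
        np.testing.assert_allclose(plus.bins[::-1], minus.bins)

    def test_truncated_anchor_contributes_only_defined_bins(self):
        prof = anchor_profile(self._uniform_track(1.0), [("chr1", 2000, "+")], 5000)
        # bins before the chromosome start have no contributing anchor
        assert prof.bins[0] == 0.0 and prof.bins[-1] == 1.0

    def test_zero_anchors_is_an_error(self):
        with pytest.raises(ValueError):
            anchor_profile(self._uniform_track(), [], 5000)


class TestRegionFpkm:
    def test_zero_count_floor_is_exactly_the_pseudocount(self):
        assert region_fpkm(0, 1000, LibraryStats(100_000_000)) == 0.01

    def test_worked_example(self):
        assert region_fpkm(200, 2000, LibraryStats(50_000_000)) == pytest.approx(2.01)

    def test_floor_is_depth_and_length_independent(self):
        assert region_fpkm(0, 500, LibraryStats(200_000_000)) == 0.01

    def test_strictly_increasing_in_count(self):
        stats = LibraryStats(1_000_000)
        values = [region_fpkm(k, 1000, stats) for k in range(0, 50, 5)]
        assert all(b > a for a, b in zip(values, values[1:]))


def test_tagalign_round_trip(tmp_path):
    tags = Tags.from_records(
        [tag("chr1", 10, 46, "+"), tag("chr1", 99, 135, "-"), tag("chr2", 0, 36, "+")]
    )
    p = tmp_path / "t.tagAlign"
    write_tagalign(p, tags)
    back = read_tagalign(p)
    assert back.to_records() == tags.to_records()
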