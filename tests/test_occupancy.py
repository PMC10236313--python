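"""Binding-site classification, top-N selection, promoter signal ratios."""

import numpy as np
import pytest

from enhancerkit.core import (
    GeneModel,
    GenomeLayout,
    Interval,
    Peak,
    promoter_region,
)
from enhancerkit.enhancers import EnhancerCall
from enhancerkit.occupancy import (
    classify_binding_sites,
    colocalization_fractions,
    compare_promoter_sets,
    promoter_signal_ratio,
    stratify_enhancers_by_binding,
    top_n_sites,
)
from enhancerkit.signal import CoverageTrack, LibraryStats, bin_counts, rpm_normalize

LAYOUT = GenomeLayout.from_pairs([("chr1", 1_000_000)])
GENE = GeneModel("g1", Interval("chr1", 500_000, 520_000), "+")
PROMOTERS = [promoter_region(GENE, LAYOUT)]


def enh(summit, activity="active"):
    peak = Peak(Interval("chr1", summit - 250, summit + 250), 80.0, summit=summit)
    return EnhancerCall(
        peak=peak, qualified=True, location_class="extragenic", activity_class=activity
    )


def site(start, end=None, score=50.0):
    return Peak(Interval("chr1", start, end or start + 400), score)


class TestClassification:
    ENHANCERS = [enh(100_000)]

    def test_enhancer_overlap(self):
        (a,) = classify_binding_sites([site(99_900)], self.ENHANCERS, PROMOTERS)
        assert a.category == "enhancer"

    def test_promoter_window_overlap(self):
        (a,) = classify_binding_sites([site(500_500)], self.ENHANCERS, PROMOTERS)
        assert a.category == "promoter"

    def test_neither_is_other(self):
        (a,) = classify_binding_sites([site(300_000)], self.ENHANCERS, PROMOTERS)
        assert a.category == "other"

    def test_promoter_takes_precedence_over_enhancer(self):
        overlapping_enh = [enh(500_200)]  # pathological: enhancer inside promoter
        (a,) = classify_binding_sites([site(500_100)], overlapping_enh, PROMOTERS)
        assert a.category == "promoter"

    def test_ranks_are_unique_and_score_ordered(self):
        sites = [site(1000, score=10), site(5000, score=30), site(9000, score=30)]
        anns = classify_binding_sites(sites, self.ENHANCERS, PROMOTERS)
        ranks = {a.site.interval.start: a.rank_by_score for a in anns}
        assert ranks[5000] == 1 and ranks[9000] == 2 and ranks[1000] == 3


class TestTopN:
    def test_selects_highest_scores(self):
        sites = [site(i * 1000, score=float(i)) for i in range(1, 11)]
        top = top_n_sites(sites, 3)
        assert [p.score for p in top] == [10.0, 9.0, 8.0]

    def test_score_tie_keeps_lower_coordinate(self):
        sites = [site(9000, score=5), site(1000, score=5)]
        top = top_n_sites(sites, 1)
        assert top[0].interval.start == 1000

    def test_n_larger_than_set_warns_and_returns_all(self):
        with pytest.warns(UserWarning):
            top = top_n_sites([site(1000)], 5)
        assert len(top) == 1

    def test_nonpositive_n_is_an_error(self):
        with pytest.raises(ValueError):
            top_n_sites([site(1000)], 0)

    def test_stable_under_input_permutation(self):
        rng = np.random.default_rng(16)
        sites = [site(int(s), score=float(sc)) for s, sc in
                 zip(rng.integers(0, 900_000, 50), rng.integers(0, 5, 50))]
        a = top_n_sites(sites, 10)
        b = top_n_sites(sites[::-1], 10)
        assert [p.interval for p in a] == [p.interval for p in b]


class TestFractions:
    def test_percentages(self):
        anns = classify_binding_sites(
            [site(100_000 + i * 10) for i in range(7)]
            + [site(500_500)]
            + [site(300_000), site(310_000)],
            [enh(100_000)],
            PROMOTERS,
        )
        fracs = colocalization_fractions(anns)
        assert fracs == {"enhancer": 70.0, "promoter": 10.0, "other": 20.0}

    def test_fractions_sum_to_one_hundred(self, pipeline_run):
        _, res, _ = pipeline_run
        for fracs in res.colocalization.values():
            assert sum(fracs.values()) == pytest.approx(100.0, abs=0.1)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError):
            colocalization_fractions([])


class TestStratify:
    def test_bound_flag_and_class_fractions(self):
        enhancers = [enh(100_000, "active"), enh(200_000, "active"), enh(300_000, "poised")]
        flags, fracs = stratify_enhancers_by_binding(enhancers, [site(99_900)])
        assert flags[enhancers[0].id] is True
        assert fracs["active"] == pytest.approx(0.5)
        assert fracs["poised"] == 0.0
        assert fracs["intermediate"] is None  # no enhancer in that class
        assert fracs["overall"] == pytest.approx(1 / 3)


def _rpm_track(values_by_bin, total=1_000_000, bin_size=100):
    vec = np.zeros(10_000)
    for b, v in values_by_bin.items():
        vec[b] = v
    return CoverageTrack(LAYOUT, bin_size, {"chr1": vec}, unit="rpm")


class TestPromoterSignal:
    def test_ratio_with_pseudocount(self):
        bins = range(4990, 5210)  # covers the g1 promoter window
        ip = _rpm_track({b: 4.0 for b in bins})
        inp = _rpm_track({b: 2.0 for b in bins})
        (rec,) = promoter_signal_ratio(ip, inp, PROMOTERS)
        assert rec.ratio == pytest.approx(4.01 / 2.01)

    def test_equal_tracks_give_unity(self):
        ip = _rpm_track({b: 3.0 for b in range(4990, 5210)})
        (rec,) = promoter_signal_ratio(ip, ip, PROMOTERS)
        assert rec.ratio == pytest.approx(1.0)

    def test_empty_windows_give_unity_via_pseudocount(self):
        (rec,) = promoter_signal_ratio(_rpm_track({}), _rpm_track({}), PROMOTERS)
        assert rec.ratio == 1.0

    def test_requires_rpm_tracks(self):
        raw = bin_counts([], LAYOUT, 100)
        with pytest.raises(ValueError):
            promoter_signal_ratio(raw, raw, PROMOTERS)

    def test_invariant_to_matched_depth_scaling(self):
        from enhancerkit.core import StrandedTag

        rng = np.random.default_rng(17)
        tags = [
            StrandedTag(Interval("chr1", int(s), int(s) + 36), "+")
            for s in rng.integers(499_000, 521_000, 400)
        ]
        ip_raw = bin_counts(tags, LAYOUT, 100)
        ip_raw_3x = bin_counts(tags * 3, LAYOUT, 100)
        r1 = promoter_signal_ratio(
            rpm_normalize(ip_raw, LibraryStats(1_000_000)),
            rpm_normalize(ip_raw, LibraryStats(2_000_000)),
            PROMOTERS,
        )
        r3 = promoter_signal_ratio(
            rpm_normalize(ip_raw_3x, LibraryStats(3_000_000)),
            rpm_normalize(ip_raw_3x, LibraryStats(6_000_000)),
            PROMOTERS,
        )
        assert r1[0].ratio == pytest.approx(r3[0].ratio, rel=1e-9)


class TestCompareSets:
    def _records(self, ratios, genes=None):
        from enhancerkit.occupancy import PromoterSignalRecord

        genes = genes or [f"g{i}" for i in range(len(ratios))]
        return [
            PromoterSignalRecord(g, PROMOTERS[0], 1.0, 1.0, r)
            for g, r in zip(genes, ratios)
        ]

    def test_identical_paired_sets_guard_degenerate_p(self):
        a = self._records([1.0, 1.2, 0.8])
        out = compare_promoter_sets(a, self._records([1.0, 1.2, 0.8]), paired=True)
        assert out.difference == 0.0 and out.p_value == 1.0

    def test_paired_requires_matched_genes(self):
        a = self._records([1.0, 1.2], genes=["x", "y"])
        b = self._records([1.0, 1.2], genes=["x", "z"])
        with pytest.raises(ValueError):
            compare_promoter_sets(a, b, paired=True)

    def test_unpaired_accepts_unequal_sizes(self):
        rng = np.random.default_rng(18)
        a = self._records(list(rng.normal(0.5, 0.05, 46)))
        b = self._records(list(rng.normal(1.0, 0.05, 67)))
        out = compare_promoter_sets(a, b, paired=False)
        assert out.n_a == 46 and out.n_b == 67
        assert out.p_value < 1e-6 and out.difference < 0
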