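"""Enhancer qualification rules, locational split, activity classes."""

import numpy as np
import pytest

from enhancerkit.core import GeneModel, Interval, MissingAnnotationError, Peak
from enhancerkit.enhancers import (
    EnhancerRuleConfig,
    assign_activity_class,
    qualify_enhancers,
    split_location_class,
)

GENES = [
    GeneModel("r1", Interval("chr1", 100_000, 120_000), "+", "refseq_like"),
    GeneModel("e1", Interval("chr1", 300_000, 310_000), "+", "est_like"),
]
ME3 = [Peak(Interval("chr1", 99_500, 100_500))]
ME1 = [Peak(Interval("chr1", 149_000, 151_000))]


def p300(start, end, score=75.0):
    return Peak(Interval("chr1", start, end), score=score)


class TestQualification:
    def test_peak_meeting_all_criteria_qualifies(self):
        (call,) = qualify_enhancers([p300(149_500, 150_000)], ME3, ME1, GENES)
        assert call.qualified and not call.rejection_reasons

    def test_score_below_floor_is_rejected(self):
        (call,) = qualify_enhancers([p300(149_500, 150_000, score=55)], ME3, ME1, GENES)
        assert call.rejection_reasons == {"low_score"}

    def test_refseq_tss_within_radius_is_rejected(self):
        # peak 800 bp upstream of the r1 TSS at 100,000
        me1 = ME1 + [Peak(Interval("chr1", 98_500, 99_300))]
        (call,) = qualify_enhancers([p300(98_700, 99_200)], [], me1, GENES)
        assert call.rejection_reasons == {"refseq_tss_proximity"}

    def test_est_tss_radius_is_wider_than_refseq(self):
        # 1.5 kb from the EST TSS at 300,000: inside 2 kb EST radius only
        me1 = ME1 + [Peak(Interval("chr1", 297_900, 298_600))]
        (call,) = qualify_enhancers([p300(298_000, 298_500)], [], me1, GENES)
        assert call.rejection_reasons == {"est_tss_proximity"}

    def test_h3k4me3_overlap_and_missing_me1_both_recorded(self):
        me3 = [Peak(Interval("chr1", 149_900, 150_200))]
        (call,) = qualify_enhancers([p300(149_500, 150_000)], me3, [], GENES)
        assert call.rejection_reasons == {"h3k4me3_overlap", "no_h3k4me1"}

    def test_missing_me1_peak_set_is_an_error(self):
        with pytest.raises(MissingAnnotationError):
            qualify_enhancers([p300(149_500, 150_000)], ME3, None, GENES)

    def test_unannotated_chromosome_is_unassignable(self):
        peak = Peak(Interval("chrUn", 1000, 1500), score=80)
        me1 = [Peak(Interval("chrUn", 900, 1600))]
        (call,) = qualify_enhancers([peak], [], me1, GENES)
        assert call.rejection_reasons == {"unassignable"}

    def test_raising_min_score_never_grows_the_qualified_set(self):
        rng = np.random.default_rng(4)
        peaks = [
            p300(int(s), int(s) + 400, score=float(sc))
            for s, sc in zip(
                rng.integers(130_000, 290_000, 200), rng.uniform(40, 120, 200)
            )
        ]
        me1 = [Peak(Interval("chr1", 125_000, 295_000))]
        previous = None
        for floor in (40, 60, 80, 100):
            cfg = EnhancerRuleConfig(min_score=floor)
            ids = {
                c.id for c in qualify_enhancers(peaks, ME3, me1, GENES, cfg) if c.qualified
            }
            if previous is not None:
                assert ids <= previous
            previous = ids

    def test_matches_brute_force_predicate_evaluation(self):
        """Oracle equivalence on 1,000 random synthetic peaks."""
        rng = np.random.default_rng(5)
        genes = [
            GeneModel(
                f"g{i}",
                Interval("chr1", int(s), int(s) + 5_000),
                "+" if rng.random() < 0.5 else "-",
                "refseq_like" if rng.random() < 0.7 else "est_like",
            )
            for i, s in enumerate(rng.integers(0, 2_000_000, 120))
        ]
        me3 = [
            Peak(Interval("chr1", int(s), int(s) + 800))
            for s in rng.integers(0, 2_000_000, 80)
        ]
        me1 = [
            Peak(Interval("chr1", int(s), int(s) + 1_500))
            for s in rng.integers(0, 2_000_000, 300)
        ]
        peaks = [
            p300(int(s), int(s) + 400, score=float(sc))
            for s, sc in zip(
                rng.integers(0, 2_000_000, 1000), rng.uniform(30, 150, 1000)
            )
        ]
        cfg = EnhancerRuleConfig()
        calls = qualify_enhancers(peaks, me3, me1, genes, cfg)
        for peak, call in zip(peaks, calls):
            iv = peak.interval
            expected = set()
            if peak.score < cfg.min_score:
                expected.add("low_score")
            if any(iv.overlaps(m.interval) for m in me3):
                expected.add("h3k4me3_overlap")
            refseq_d = min(
                iv.distance_to_point("chr1", g.tss)
                for g in genes
                if g.source == "refseq_like"
            )
            if refseq_d < cfg.refseq_tss_radius:
                expected.add("refseq_tss_proximity")
            est_d = min(
                iv.distance_to_point("chr1", g.tss)
                for g in genes
                if g.source == "est_like"
            )
            if est_d < cfg.est_tss_radius:
                expected.add("est_tss_proximity")
            if not any(iv.overlaps(m.interval) for m in me1):
                expected.add("no_h3k4me1")
            assert set(call.rejection_reasons) == expected
            assert call.qualified == (not expected)


class TestLocationClass:
    def _qualified(self, start, end):
        me1 = [Peak(Interval("chr1", start - 100, end + 100))]
        (call,) = qualify_enhancers([p300(start, end)], [], me1, GENES)
        assert call.qualified
        return call

    def test_contained_in_gene_body_is_intragenic(self):
        (call,) = split_location_class([self._qualified(110_000, 110_500)], GENES)
        assert call.location_class == "intragenic"

    def test_far_from_all_genes_is_extragenic(self):
        (call,) = split_location_class([self._qualified(200_000, 200_500)], GENES)
        assert call.location_class == "extragenic"

    def test_near_transcription_end_site_is_excluded(self):
        # r1 TES at 119,999; peak 3 kb downstream, outside the body
        (call,) = split_location_class([self._qualified(123_000, 123_500)], GENES)
        assert call.location_class == "excluded_near_tes"

    def test_classes_partition_qualified_calls(self, pipeline_run):
        _, res, _ = pipeline_run
        for c in res.qualified:
            assert c.location_class in ("intragenic", "extragenic", "excluded_near_tes")


class TestActivityClass:
    def _call(self):
        me1 = [Peak(Interval("chr1", 199_000, 201_000))]
        (call,) = qualify_enhancers([p300(199_800, 200_200)], [], me1, GENES)
        return call

    @pytest.mark.parametrize(
        "ac,me,expected",
        [
            (True, False, "active"),
            (False, True, "poised"),
            (False, False, "intermediate"),
            (True, True, "conflicted"),
        ],
    )
    def test_mark_overlap_combinations(self, ac, me, expected):
        ac_peaks = [Peak(Interval("chr1", 199_900, 200_100))] if ac else []
        me_peaks = [Peak(Interval("chr1", 199_900, 200_100))] if me else []
        (call,) = assign_activity_class([self._call()], ac_peaks, me_peaks)
        assert call.activity_class == expected
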