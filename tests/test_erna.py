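"""Summit-anchored eRNA window counting, exclusion filters, induction."""

import dataclasses

import numpy as np
import pytest

from enhancerkit.core import GenomeLayout, Interval, IntervalIndex, Peak, StrandedTag
from enhancerkit.enhancers import EnhancerCall
from enhancerkit.erna import (
    ErnaFilterConfig,
    ErnaLocus,
    apply_erna_filters,
    build_erna_loci,
    erna_induction,
    evaluate_exclusions,
)
from enhancerkit.signal import LibraryStats, Tags, region_fpkm

LAYOUT = GenomeLayout.from_pairs([("chr1", 1_000_000)])


def enhancer(summit, chrom="chr1"):
    peak = Peak(Interval(chrom, summit - 250, summit + 250), 80.0, summit=summit)
    return EnhancerCall(peak=peak, qualified=True, location_class="extragenic")


def rna(*positions_strands):
    return Tags.from_records(
        [
            StrandedTag(Interval("chr1", p, p + 36), s)
            for p, s in positions_strands
        ]
    )


class TestBuildLoci:
    def test_window_membership(self):
        tags = rna((100_500, "+"), (101_200, "+"), (99_100, "-"))
        (locus,) = build_erna_loci([enhancer(100_000)], tags, LibraryStats(10_000), LAYOUT)
        assert locus.plus_down_counts == 2
        assert locus.minus_up_counts == 1
        assert locus.plus_far_counts == 0 and locus.minus_far_counts == 0

    def test_strand_is_respected(self):
        tags = rna((100_500, "-"), (99_100, "+"))  # wrong strands for both windows
        (locus,) = build_erna_loci([enhancer(100_000)], tags, LibraryStats(10_000), LAYOUT)
        assert locus.plus_down_counts == 0 and locus.minus_up_counts == 0

    def test_minus_window_clamped_at_chromosome_start(self):
        (locus,) = build_erna_loci([enhancer(1000)], rna(), LibraryStats(10_000), LAYOUT)
        assert locus.minus_up_len == 1000
        assert locus.fpkm_minus == region_fpkm(0, 1000, LibraryStats(10_000))

    def test_no_tags_floors_both_fpkm_at_pseudocount(self):
        (locus,) = build_erna_loci([enhancer(100_000)], rna(), LibraryStats(10_000), LAYOUT)
        assert locus.fpkm_plus == 0.01 and locus.fpkm_minus == 0.01


def make_locus(plus_down=10, minus_up=10, plus_far=0, minus_far=0, **kw):
    defaults = dict(
        plus_down_counts=plus_down,
        minus_up_counts=minus_up,
        plus_far_counts=plus_far,
        minus_far_counts=minus_far,
        fpkm_plus=0.01,
        fpkm_minus=0.01,
    )
    defaults.update(kw)
    return ErnaLocus(enhancer=enhancer(100_000), summit=100_000, **defaults)


class TestFilters:
    def test_strand_ratio_above_five_excludes(self):
        (locus,) = apply_erna_filters([make_locus(plus_down=600, minus_up=100)])
        assert locus.exclusion_reasons == {"strand_ratio"}  # 601/101 > 5

    def test_ratio_exactly_at_threshold_passes(self):
        (locus,) = apply_erna_filters([make_locus(plus_down=49, minus_up=9)])
        assert "strand_ratio" not in locus.exclusion_reasons  # 50/10 == 5, not > 5

    def test_symmetric_option_also_checks_minus_dominance(self):
        cfg = ErnaFilterConfig(symmetric_ratio=True)
        (locus,) = apply_erna_filters([make_locus(plus_down=100, minus_up=600)], cfg)
        assert "strand_ratio" in locus.exclusion_reasons

    def test_hot_flanking_window_excludes(self):
        (locus,) = apply_erna_filters([make_locus(plus_down=20, plus_far=30)])
        assert locus.exclusion_reasons == {"flanking_signal"}

    def test_flank_comparison_is_density_based_when_clamped(self):
        locus = make_locus(plus_down=20, plus_far=15, plus_far_len=1000)
        (out,) = apply_erna_filters([locus])
        # 15/1000 bp > 20/2000 bp even though the raw count is lower
        assert "flanking_signal" in out.exclusion_reasons

    def test_repeat_flag_requires_fpkm_gate(self):
        lo = make_locus(fpkm_plus=0.5, fpkm_minus=0.5)
        hi = make_locus(fpkm_plus=2.0, fpkm_minus=0.5)
        flags = {lo.id: True}
        (lo_out,) = apply_erna_filters([lo], repeat_flags=flags)
        (hi_out,) = apply_erna_filters([hi], repeat_flags=flags)
        assert "repeat_signal" not in lo_out.exclusion_reasons
        assert "repeat_signal" in hi_out.exclusion_reasons

    def test_blacklist_overlap_excludes(self):
        blacklist = [Interval("chr1", 99_000, 99_500)]  # inside the minus window
        (locus,) = apply_erna_filters([make_locus()], rrna_blacklist=blacklist)
        assert locus.exclusion_reasons == {"rrna_homology"}

    def test_balanced_clean_locus_passes(self):
        (locus,) = apply_erna_filters([make_locus(plus_down=12, minus_up=10)])
        assert locus.passed and not locus.exclusion_reasons

    def test_filters_are_idempotent(self):
        loci = [make_locus(plus_down=600, minus_up=100), make_locus()]
        once = apply_erna_filters(loci)
        snapshot = [(l.passed, set(l.exclusion_reasons)) for l in once]
        twice = apply_erna_filters(once)
        assert [(l.passed, set(l.exclusion_reasons)) for l in twice] == snapshot

    def test_matches_brute_force_predicates_on_random_loci(self):
        rng = np.random.default_rng(6)
        cfg = ErnaFilterConfig()
        for _ in range(300):
            locus = make_locus(
                plus_down=int(rng.integers(0, 100)),
                minus_up=int(rng.integers(0, 100)),
                plus_far=int(rng.integers(0, 60)),
                minus_far=int(rng.integers(0, 60)),
                fpkm_plus=float(rng.uniform(0, 3)),
                fpkm_minus=float(rng.uniform(0, 3)),
            )
            flag = bool(rng.random() < 0.3)
            got = evaluate_exclusions(locus, cfg, IntervalIndex([]), flag)
            expected = set()
            if (locus.plus_down_counts + 1) / (locus.minus_up_counts + 1) > 5:
                expected.add("strand_ratio")
            if (
                locus.plus_far_counts > locus.plus_down_counts
                or locus.minus_far_counts > locus.minus_up_counts
            ):
                expected.add("flanking_signal")
            if flag and max(locus.fpkm_plus, locus.fpkm_minus) > 1:
                expected.add("repeat_signal")
            assert got == frozenset(expected)


class TestInduction:
    def _locus_with_fpkm(self, summit, plus, minus):
        locus = make_locus(fpkm_plus=plus, fpkm_minus=minus)
        return dataclasses.replace(locus, enhancer=enhancer(summit), summit=summit)

    def test_simple_ratio(self):
        pre = [self._locus_with_fpkm(100_000, 1.0, 1.01)]
        post = [self._locus_with_fpkm(100_000, 2.0, 2.02)]
        ratios, med = erna_induction(pre, post)
        assert med == pytest.approx(2.0)

    def test_identical_conditions_give_unity(self):
        pre = [self._locus_with_fpkm(s, 1.5, 0.5) for s in (50_000, 100_000)]
        post = [dataclasses.replace(l) for l in pre]
        ratios, med = erna_induction(pre, post)
        assert all(r == pytest.approx(1.0) for r in ratios.values())

    def test_pseudocount_floors_the_denominator(self):
        pre = [self._locus_with_fpkm(100_000, 0.01, 0.01)]  # zero counts
        post = [self._locus_with_fpkm(100_000, 2.0, 0.02)]
        _, med = erna_induction(pre, post)
        assert med == pytest.approx(101.0)

    def test_unmatched_loci_raise_with_identifiers(self):
        pre = [self._locus_with_fpkm(100_000, 1.0, 1.0)]
        post = [self._locus_with_fpkm(200_000, 1.0, 1.0)]
        with pytest.raises(ValueError, match="chr1:99750-100250"):
            erna_induction(pre, post)


def test_planted_rate_recovery_within_poisson_tolerance():
    """Symmetric Poisson eRNA loci: total FPKM within 3 SE of expectation."""
    rng = np.random.default_rng(7)
    lam, n_loci, depth = 60.0, 100, 500_000
    summits = (np.arange(n_loci) + 1) * 9_000
    rows = []
    for s in summits:
        for lo, strand in ((s, "+"), (s - 2000, "-")):
            for p in rng.integers(lo, lo + 2000 - 36, rng.poisson(lam)):
                rows.append(StrandedTag(Interval("chr1", int(p), int(p) + 36), strand))
    tags = Tags.from_records(rows)
    stats = LibraryStats(depth)
    loci = build_erna_loci([enhancer(int(s)) for s in summits], tags, stats, LAYOUT)
    scale = 1e9 / (2000 * depth)
    expected = 2 * lam * scale + 0.02
    se = np.sqrt(2 * lam) * scale
    hits = sum(abs(l.total_fpkm - expected) <= 3 * se for l in loci)
    assert hits / n_loci >= 0.95
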