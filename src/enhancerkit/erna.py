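"""Summit-anchored, strand-aware eRNA quantification and exclusion filters.

eRNAs are short (<2 kb) bidirectional transcripts at enhancer centers, so
quantification uses four fixed windows around the p300 summit: the
proximal pair (+ strand [summit, summit+2kb), - strand [summit-2kb,
summit)) and the distal pair 2-4 kb out on each side, used to reject
read-through from long or genic transcripts. A tag is counted in a window
when its 5' position lies inside it.

Four exclusion filters are applied, each recorded independently:
strand_ratio (unidirectional signal, ratio > 5 with a 1-tag pseudocount),
flanking_signal (distal window hotter than its proximal window),
repeat_signal (flagged repetitive locus with >1 FPKM), and rrna_homology
(any window overlapping the rRNA blacklist).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

from .core import GenomeLayout, Interval, IntervalIndex
from .enhancers import EnhancerCall
from .signal import LibraryStats, Tags, count_tags_in_window, region_fpkm

PROXIMAL_BP = 2000
DISTAL_BP = 4000

ExclusionReason = str  # {strand_ratio, flanking_signal, repeat_signal, rrna_homology}


@dataclass
class ErnaFilterConfig:
    ratio_threshold: float = 5.0
    ratio_pseudocount: float = 1.0
    fpkm_repeat_threshold: float = 1.0
    symmetric_ratio: bool = False

    def __post_init__(self) -> None:
        if self.ratio_threshold <= 0 or self.fpkm_repeat_threshold <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class ErnaLocus:
    enhancer: EnhancerCall
    summit: int
    plus_down_counts: int = 0
    minus_up_counts: int = 0
    plus_far_counts: int = 0
    minus_far_counts: int = 0
    plus_down_len: int = PROXIMAL_BP
    minus_up_len: int = PROXIMAL_BP
    plus_far_len: int = PROXIMAL_BP
    minus_far_len: int = PROXIMAL_BP
    fpkm_plus: float = 0.0
    fpkm_minus: float = 0.0
    passed: bool = False
    exclusion_reasons: frozenset[str] = frozenset()

    @property
    def id(self) -> str:
        return self.enhancer.id

    @property
    def total_fpkm(self) -> float:
        return self.fpkm_plus + self.fpkm_minus

    def windows(self) -> list[Interval]:
        """The (clamped, non-empty) quantification windows of this locus."""
        chrom = self.enhancer.peak.interval.chrom
        s = self.summit
        raw = [
            (s, s + PROXIMAL_BP),
            (s - PROXIMAL_BP, s),
            (s + PROXIMAL_BP, s + DISTAL_BP),
            (s - DISTAL_BP, s - PROXIMAL_BP),
        ]
        out = []
        for a, b in raw:
            a = max(a, 0)
            if b > a:
                out.append(Interval(chrom, a, b))
        return out


def _clamped(start: int, end: int, length: int) -> tuple[int, int, int]:
    a, b = max(start, 0), min(end, length)
    return a, b, max(b - a, 0)


def build_erna_loci(
    enhancers: Sequence[EnhancerCall],
    rna_tags: Tags,
    stats: LibraryStats,
    layout: GenomeLayout,
) -> list[ErnaLocus]:
    """Populate the four window counts and proximal-window FPKM per enhancer.

    FPKM uses the actual clamped window length, so loci near chromosome
    ends are normalized over the bases they really cover.
    """
    loci = []
    for enh in enhancers:
        chrom = enh.peak.interval.chrom
        length = layout.length_of(chrom)
        s = enh.summit
        pd_a, pd_b, pd_len = _clamped(s, s + PROXIMAL_BP, length)
        mu_a, mu_b, mu_len = _clamped(s - PROXIMAL_BP, s, length)
        pf_a, pf_b, pf_len = _clamped(s + PROXIMAL_BP, s + DISTAL_BP, length)
        mf_a, mf_b, mf_len = _clamped(s - DISTAL_BP, s - PROXIMAL_BP, length)
        plus_down = count_tags_in_window(rna_tags, chrom, pd_a, pd_b, "+") if pd_len else 0
        minus_up = count_tags_in_window(rna_tags, chrom, mu_a, mu_b, "-") if mu_len else 0
        plus_far = count_tags_in_window(rna_tags, chrom, pf_a, pf_b, "+") if pf_len else 0
        minus_far = count_tags_in_window(rna_tags, chrom, mf_a, mf_b, "-") if mf_len else 0
        loci.append(
            ErnaLocus(
                enhancer=enh,
                summit=s,
                plus_down_counts=plus_down,
                minus_up_counts=minus_up,
                plus_far_counts=plus_far,
                minus_far_counts=minus_far,
                plus_down_len=pd_len,
                minus_up_len=mu_len,
                plus_far_len=pf_len,
                minus_far_len=mf_len,
                fpkm_plus=region_fpkm(plus_down, max(pd_len, 1), stats),
                fpkm_minus=region_fpkm(minus_up, max(mu_len, 1), stats),
            )
        )
    return loci


def _density(count: int, length: int) -> float:
    return count / length if length > 0 else 0.0


def evaluate_exclusions(
    locus: ErnaLocus,
    cfg: ErnaFilterConfig,
    blacklist: IntervalIndex,
    repeat_flag: bool,
) -> frozenset[str]:
    """All applicable exclusion reasons for one locus (no short-circuit)."""
    reasons: set[str] = set()
    pc = cfg.ratio_pseudocount
    ratio = (locus.plus_down_counts + pc) / (locus.minus_up_counts + pc)
    tripped = ratio > cfg.ratio_threshold
    if cfg.symmetric_ratio:
        tripped = tripped or (1.0 / ratio) > cfg.ratio_threshold
    if tripped:
        reasons.add("strand_ratio")

    equal_lengths = (
        locus.plus_down_len == locus.plus_far_len == locus.minus_up_len == locus.minus_far_len
    )
    if equal_lengths:
        flank_hot = (
            locus.plus_far_counts > locus.plus_down_counts
            or locus.minus_far_counts > locus.minus_up_counts
        )
    else:
        # length-normalize when clamping makes windows unequal
        flank_hot = _density(locus.plus_far_counts, locus.plus_far_len) > _density(
            locus.plus_down_counts, locus.plus_down_len
        ) or _density(locus.minus_far_counts, locus.minus_far_len) > _density(
            locus.minus_up_counts, locus.minus_up_len
        )
    if flank_hot:
        reasons.add("flanking_signal")

    if repeat_flag and max(locus.fpkm_plus, locus.fpkm_minus) > cfg.fpkm_repeat_threshold:
        reasons.add("repeat_signal")

    if any(blacklist.overlaps(w) for w in locus.windows()):
        reasons.add("rrna_homology")
    return frozenset(reasons)


def apply_erna_filters(
    loci: Iterable[ErnaLocus],
    cfg: ErnaFilterConfig = ErnaFilterConfig(),
    rrna_blacklist: Sequence[Interval] | IntervalIndex = (),
    repeat_flags: Optional[Mapping[str, bool]] = None,
) -> list[ErnaLocus]:
    """Set passed/exclusion_reasons on every locus. Idempotent."""
    idx = (
        rrna_blacklist
        if isinstance(rrna_blacklist, IntervalIndex)
        else IntervalIndex(rrna_blacklist)
    )
    repeat_flags = repeat_flags or {}
    out = []
    for locus in loci:
        reasons = evaluate_exclusions(
            locus, cfg, idx, bool(repeat_flags.get(locus.id, False))
        )
        locus.exclusion_reasons = reasons
        locus.passed = not reasons
        out.append(locus)
    return out


def erna_induction(
    loci_unstim: Sequence[ErnaLocus], loci_stim: Sequence[ErnaLocus]
) -> tuple[dict[str, float], float]:
    """Per-locus stimulated/unstimulated total-FPKM ratio and the median.

    Loci are matched by enhancer identity; the FPKM pseudocount floors the
    denominator at 0.02 so every ratio is finite.
    """
    by_id_stim = {l.id: l for l in loci_stim}
    missing = [l.id for l in loci_unstim if l.id not in by_id_stim]
    extra = [i for i in by_id_stim if i not in {l.id for l in loci_unstim}]
    if missing or extra:
        raise ValueError(f"unmatched eRNA loci: missing={missing} extra={extra}")
    ratios = {
        l.id: by_id_stim[l.id].total_fpkm / l.total_fpkm for l in loci_unstim
    }
    return ratios, float(median(ratios.values())) if ratios else float("nan")
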