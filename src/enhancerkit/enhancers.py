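"""Enhancer definition: qualification of p300 peaks, locational split,
and activity-class assignment.

A p300 peak qualifies as an enhancer iff it (1) meets the caller score
floor, (2) does not overlap any H3K4me3 peak from any condition, (3) is
not within the RefSeq TSS radius, (4) is not within the spliced-EST TSS
radius, and (5) overlaps an H3K4me1 peak from some condition. All failing
criteria are recorded; evaluation never short-circuits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .core import (
    GeneModel,
    Interval,
    IntervalIndex,
    MissingAnnotationError,
    Peak,
)

RejectionReason = Literal[
    "low_score",
    "h3k4me3_overlap",
    "refseq_tss_proximity",
    "est_tss_proximity",
    "no_h3k4me1",
    "unassignable",
]

LocationClass = Literal["intragenic", "extragenic", "excluded_near_tes", "unassigned"]
ActivityClass = Literal["active", "intermediate", "poised", "conflicted"]


@dataclass
class EnhancerRuleConfig:
    min_score: float = 60.0
    refseq_tss_radius: int = 1000
    est_tss_radius: int = 2000
    tes_exclusion_radius: int = 5000

    def __post_init__(self) -> None:
        if min(self.refseq_tss_radius, self.est_tss_radius, self.tes_exclusion_radius) < 0:
            raise ValueError("radii must be >= 0")


@dataclass
class EnhancerCall:
    peak: Peak
    qualified: bool = False
    rejection_reasons: frozenset[str] = frozenset()
    location_class: LocationClass = "unassigned"
    activity_class: Optional[ActivityClass] = None
    epu_gene: Optional[str] = None
    inducible: bool = False
    bound: bool = False

    @property
    def id(self) -> str:
        iv = self.peak.interval
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    @property
    def summit(self) -> int:
        return self.peak.resolved_summit


def _tss_points_by_chrom(
    genes: Sequence[GeneModel], source: str
) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for g in genes:
        if g.source == source:
            out.setdefault(g.interval.chrom, []).append(g.tss)
    return out


def _min_point_distance(iv: Interval, points: dict[str, list[int]]) -> float:
    pts = points.get(iv.chrom)
    if not pts:
        return float("inf")
    return min(iv.distance_to_point(iv.chrom, p) for p in pts)


def qualify_enhancers(
    p300: Sequence[Peak],
    h3k4me3_all_conditions: Sequence[Peak],
    h3k4me1_any_condition: Optional[Sequence[Peak]],
    genes: Sequence[GeneModel],
    cfg: EnhancerRuleConfig = EnhancerRuleConfig(),
) -> list[EnhancerCall]:
    """Evaluate all qualification criteria on every p300 peak.

    H3K4me3 peaks are the union over all supplied conditions (the stricter
    reading of "any condition"). Peaks on chromosomes that carry no gene
    annotation at all are rejected ``unassignable`` because the TSS
    criteria cannot be certified there.
    """
    if h3k4me1_any_condition is None:
        raise MissingAnnotationError("H3K4me1 peak set is required")
    if not genes:
        raise MissingAnnotationError("gene annotation is required")
    me3_idx = IntervalIndex(p.interval for p in h3k4me3_all_conditions)
    me1_idx = IntervalIndex(p.interval for p in h3k4me1_any_condition)
    refseq_tss = _tss_points_by_chrom(genes, "refseq_like")
    est_tss = _tss_points_by_chrom(genes, "est_like")
    annotated_chroms = {g.interval.chrom for g in genes}

    calls = []
    for peak in p300:
        iv = peak.interval
        reasons: set[str] = set()
        if peak.score < cfg.min_score:
            reasons.add("low_score")
        if me3_idx.overlaps(iv):
            reasons.add("h3k4me3_overlap")
        if iv.chrom not in annotated_chroms:
            reasons.add("unassignable")
        else:
            if _min_point_distance(iv, refseq_tss) < cfg.refseq_tss_radius:
                reasons.add("refseq_tss_proximity")
            if _min_point_distance(iv, est_tss) < cfg.est_tss_radius:
                reasons.add("est_tss_proximity")
        if not me1_idx.overlaps(iv):
            reasons.add("no_h3k4me1")
        calls.append(
            EnhancerCall(
                peak=peak,
                qualified=not reasons,
                rejection_reasons=frozenset(reasons),
            )
        )
    return calls


def split_location_class(
    calls: Iterable[EnhancerCall],
    genes: Sequence[GeneModel],
    cfg: EnhancerRuleConfig = EnhancerRuleConfig(),
) -> list[EnhancerCall]:
    """Set location_class on qualified calls.

    Intragenic: fully contained in a RefSeq-like transcription unit.
    Otherwise excluded_near_tes when within the TES exclusion radius of a
    RefSeq-like transcription end site (to keep strong 3'-end RNAPII signal
    out of profiles); else extragenic.
    """
    refseq = [g for g in genes if g.source == "refseq_like"]
    body_idx = IntervalIndex(g.interval for g in refseq)
    tes_points: dict[str, list[int]] = {}
    for g in refseq:
        tes_points.setdefault(g.interval.chrom, []).append(g.tes)

    out = []
    for call in calls:
        if not call.qualified:
            out.append(call)
            continue
        iv = call.peak.interval
        contained = any(
            h.start <= iv.start and iv.end <= h.end for h in body_idx.hits(iv)
        )
        if contained:
            call.location_class = "intragenic"
        elif _min_point_distance(iv, tes_points) < cfg.tes_exclusion_radius:
            call.location_class = "excluded_near_tes"
        else:
            call.location_class = "extragenic"
        out.append(call)
    return out


def assign_activity_class(
    calls: Iterable[EnhancerCall],
    active_mark_peaks: Sequence[Peak],
    repressive_mark_peaks: Sequence[Peak],
) -> list[EnhancerCall]:
    """Classify qualified enhancers by acetylation/repressive-mark overlap.

    Default marks are H3K9ac (active) vs H3K9me3 (poised); the same engine
    serves an H3K27ac/H3K27me3 classing. Overlap with both marks is
    surfaced as ``conflicted`` rather than silently resolved.
    """
    ac_idx = IntervalIndex(p.interval for p in active_mark_peaks)
    me_idx = IntervalIndex(p.interval for p in repressive_mark_peaks)
    out = []
    for call in calls:
        if not call.qualified:
            out.append(call)
            continue
        has_ac = ac_idx.overlaps(call.peak.interval)
        has_me = me_idx.overlaps(call.peak.interval)
        if has_ac and has_me:
            call.activity_class = "conflicted"
        elif has_ac:
            call.activity_class = "active"
        elif has_me:
            call.activity_class = "poised"
        else:
            call.activity_class = "intermediate"
        out.append(call)
    return out
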