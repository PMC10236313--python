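"""Binding-site occupancy and input-normalized promoter signal dynamics.

Classifies factor binding sites against promoter windows and qualified
enhancers (promoter takes precedence), computes colocalization fraction
vectors and top-N subsets, stratifies enhancers by binding, and
quantifies input-normalized promoter signal (e.g. H3K9me2) with paired or
unpaired set contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import (
    BoundsError,
    Interval,
    IntervalIndex,
    Peak,
    PromoterRegion,
)
from .enhancers import EnhancerCall
from .signal import CoverageTrack

Category = Literal["enhancer", "promoter", "other"]

DEFAULT_EPSILON_RPM = 0.01


@dataclass
class BindingSiteAnnotation:
    site: Peak
    category: Category
    condition: str = ""
    rank_by_score: int = 0


@dataclass
class PromoterSignalRecord:
    gene: str
    window: PromoterRegion
    ip_rpm: float
    input_rpm: float
    ratio: float
    condition: str = ""


@dataclass
class SetContrast:
    mean_a: float
    mean_b: float
    difference: float
    p_value: float
    n_a: int
    n_b: int
    paired: bool


def classify_binding_sites(
    sites: Sequence[Peak],
    enhancers: Sequence[EnhancerCall],
    promoters: Sequence[PromoterRegion],
    condition: str = "",
) -> list[BindingSiteAnnotation]:
    """Assign each site exactly one category.

    Promoter wins over enhancer when a site touches both universes (they
    are near-disjoint by construction of the enhancer definition). Ranks
    are by descending score with (chrom, start) as the deterministic
    tie-break.
    """
    prom_idx = IntervalIndex(p.interval for p in promoters)
    enh_idx = IntervalIndex(e.peak.interval for e in enhancers if e.qualified)
    order = sorted(
        range(len(sites)),
        key=lambda i: (-sites[i].score, sites[i].interval.chrom, sites[i].interval.start),
    )
    rank = {idx: r + 1 for r, idx in enumerate(order)}
    out = []
    for i, site in enumerate(sites):
        if prom_idx.overlaps(site.interval):
            cat: Category = "promoter"
        elif enh_idx.overlaps(site.interval):
            cat = "enhancer"
        else:
            cat = "other"
        out.append(
            BindingSiteAnnotation(site, cat, condition=condition, rank_by_score=rank[i])
        )
    return out


def top_n_sites(sites: Sequence[Peak], n: int) -> list[Peak]:
    """The n highest-score sites; ties break toward the lower coordinate."""
    if n <= 0:
        raise ValueError("n must be >= 1")
    ranked = sorted(
        sites, key=lambda p: (-p.score, p.interval.chrom, p.interval.start)
    )
    if n > len(ranked):
        import warnings

        warnings.warn(
            f"requested top {n} sites but only {len(ranked)} exist", stacklevel=2
        )
    return ranked[:n]


def colocalization_fractions(
    annotations: Sequence[BindingSiteAnnotation],
) -> dict[Category, float]:
    """Percentages of sites per category; sums to 100 within rounding."""
    if not annotations:
        raise ValueError("no annotations to summarize")
    n = len(annotations)
    return {
        cat: 100.0 * sum(a.category == cat for a in annotations) / n
        for cat in ("enhancer", "promoter", "other")
    }


def stratify_enhancers_by_binding(
    enhancers: Sequence[EnhancerCall], sites: Sequence[Peak]
) -> tuple[dict[str, bool], dict[str, Optional[float]]]:
    """Flag each qualified enhancer as bound (>= 1 bp site overlap).

    Returns (per-enhancer bound flags, bound fractions per activity class
    plus 'overall'); a class with zero enhancers reports None.
    """
    site_idx = IntervalIndex(s.interval for s in sites)
    flags: dict[str, bool] = {}
    by_class: dict[str, list[bool]] = {}
    for enh in enhancers:
        if not enh.qualified:
            continue
        bound = site_idx.overlaps(enh.peak.interval)
        enh.bound = bound
        flags[enh.id] = bound
        if enh.activity_class is not None:
            by_class.setdefault(enh.activity_class, []).append(bound)
    fractions: dict[str, Optional[float]] = {}
    for cls in ("active", "intermediate", "poised", "conflicted"):
        vals = by_class.get(cls, [])
        fractions[cls] = (sum(vals) / len(vals)) if vals else None
    fractions["overall"] = (sum(flags.values()) / len(flags)) if flags else None
    return flags, fractions


def promoter_signal_ratio(
    ip_track: CoverageTrack,
    input_track: CoverageTrack,
    promoters: Sequence[PromoterRegion],
    epsilon: float = DEFAULT_EPSILON_RPM,
    condition: str = "",
) -> list[PromoterSignalRecord]:
    """Input-normalized promoter signal: (mean IP RPM + e)/(mean input RPM + e).

    Both tracks must already be RPM-normalized against their own library
    sizes; the symmetric pseudo-RPM epsilon keeps ratios finite and makes
    the empty-window ratio exactly 1.
    """
    if ip_track.unit != "rpm" or input_track.unit != "rpm":
        raise ValueError("promoter_signal_ratio requires RPM-normalized tracks")
    bs = ip_track.bin_size
    out = []
    for prom in promoters:
        iv = prom.interval
        if iv.chrom not in ip_track.layout:
            raise BoundsError(f"promoter window {iv} outside layout")
        lo, hi = iv.start // bs, -(-iv.end // bs)
        ip = float(np.mean(ip_track.vector(iv.chrom)[lo:hi]))
        inp = float(np.mean(input_track.vector(iv.chrom)[lo:hi]))
        out.append(
            PromoterSignalRecord(
                gene=prom.gene.name,
                window=prom,
                ip_rpm=ip,
                input_rpm=inp,
                ratio=(ip + epsilon) / (inp + epsilon),
                condition=condition,
            )
        )
    return out


def compare_promoter_sets(
    records_a: Sequence[PromoterSignalRecord],
    records_b: Sequence[PromoterSignalRecord],
    paired: bool = False,
) -> SetContrast:
    """Contrast two promoter-signal sets (means, difference, t-test).

    Paired mode requires matched gene lists (same genes, same order after
    sorting); degenerate zero-variance contrasts report p = 1.
    """
    if len(records_a) < 2 or len(records_b) < 2:
        raise ValueError("each set needs >= 2 records")
    a = np.asarray([r.ratio for r in records_a], dtype=float)
    b = np.asarray([r.ratio for r in records_b], dtype=float)
    import warnings

    if paired:
        genes_a = [r.gene for r in records_a]
        genes_b = [r.gene for r in records_b]
        if sorted(genes_a) != sorted(genes_b):
            raise ValueError("paired contrast requires matched gene lists")
        order_b = {g: i for i, g in enumerate(genes_b)}
        b = b[[order_b[g] for g in genes_a]]
        with warnings.catch_warnings():
            # near-identical pairs trip scipy's precision warning; the
            # degenerate zero-variance case is guarded below (p -> 1)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sps.ttest_rel(a, b)
    else:
        res = sps.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return SetContrast(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        difference=float(a.mean() - b.mean()),
        p_value=p,
        n_a=len(a),
        n_b=len(b),
        paired=paired,
    )
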