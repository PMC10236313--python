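"""Enhancer-promoter-unit assignment via CTCF-delimited blocks.

CTCF insulator summits partition each chromosome into blocks that tile it
without overlap (chromosome ends close the terminal blocks). An
extragenic enhancer is assigned to the nearest gene TSS that shares its
block and lies within a configurable range cap; crossing a CTCF boundary
or exceeding the cap leaves it unassigned with a recorded reason.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import BoundsError, GenomeLayout, GeneModel, Interval, Peak
from .enhancers import EnhancerCall

DEFAULT_MAX_RANGE = 200_000


@dataclass
class CtcfBlock:
    interval: Interval
    member_tss: list[str] = field(default_factory=list)
    member_enhancers: list[str] = field(default_factory=list)


@dataclass
class EpuAssignment:
    enhancer_id: str
    gene: Optional[str]
    distance: Optional[int]
    reason: str  # assigned_nearest_in_block | no_tss_in_block | out_of_range


def partition_by_ctcf(
    ctcf_sites: Sequence[Peak], layout: GenomeLayout
) -> list[CtcfBlock]:
    """Tile every chromosome into blocks bounded by CTCF peak summits.

    Duplicate summits collapse (no zero-length blocks); a chromosome with
    no CTCF site is one block spanning its full length.
    """
    summits: dict[str, set[int]] = {c: set() for c in layout.names}
    for p in ctcf_sites:
        chrom = p.interval.chrom
        layout.check(p.interval)
        s = p.resolved_summit
        if 0 < s < layout.length_of(chrom):
            summits[chrom].add(s)
    blocks = []
    for chrom, length in layout.chromosomes:
        bounds = [0] + sorted(summits[chrom]) + [length]
        for a, b in zip(bounds, bounds[1:]):
            blocks.append(CtcfBlock(Interval(chrom, a, b)))
    return blocks


def _block_of(blocks_by_chrom: dict[str, list[CtcfBlock]], chrom: str, point: int) -> CtcfBlock:
    chrom_blocks = blocks_by_chrom[chrom]
    starts = [b.interval.start for b in chrom_blocks]
    i = bisect.bisect_right(starts, point) - 1
    return chrom_blocks[i]


def assign_enhancers_to_genes(
    enhancers: Sequence[EnhancerCall],
    genes: Sequence[GeneModel],
    blocks: Sequence[CtcfBlock],
    layout: GenomeLayout,
    max_range: int = DEFAULT_MAX_RANGE,
) -> list[EpuAssignment]:
    """Assign each enhancer to the nearest in-block gene TSS within range.

    Distance is summit-to-TSS in bp; ties break toward the lower TSS
    coordinate. Also records block membership on the blocks themselves.
    Deterministic and invariant to input ordering.
    """
    blocks_by_chrom: dict[str, list[CtcfBlock]] = {}
    for b in sorted(blocks, key=lambda b: (b.interval.chrom, b.interval.start)):
        blocks_by_chrom.setdefault(b.interval.chrom, []).append(b)

    for g in sorted(genes, key=lambda g: (g.interval.chrom, g.tss, g.name)):
        if g.interval.chrom in blocks_by_chrom:
            _block_of(blocks_by_chrom, g.interval.chrom, g.tss).member_tss.append(g.name)

    gene_lookup = {}
    for g in genes:
        gene_lookup.setdefault(g.name, g)

    assignments = []
    for enh in sorted(enhancers, key=lambda e: (e.peak.interval.chrom, e.summit)):
        chrom = enh.peak.interval.chrom
        if chrom not in blocks_by_chrom:
            raise BoundsError(f"enhancer {enh.id} on chromosome outside layout")
        summit = enh.summit
        if not (0 <= summit < layout.length_of(chrom)):
            raise BoundsError(f"enhancer summit {summit} outside {chrom}")
        block = _block_of(blocks_by_chrom, chrom, summit)
        block.member_enhancers.append(enh.id)
        if not block.member_tss:
            assignments.append(EpuAssignment(enh.id, None, None, "no_tss_in_block"))
            continue
        candidates = sorted(
            (abs(gene_lookup[name].tss - summit), gene_lookup[name].tss, name)
            for name in block.member_tss
        )
        dist, _, name = candidates[0]
        if dist > max_range:
            assignments.append(EpuAssignment(enh.id, None, None, "out_of_range"))
        else:
            enh.epu_gene = name
            assignments.append(
                EpuAssignment(enh.id, name, dist, "assigned_nearest_in_block")
            )
    return assignments
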