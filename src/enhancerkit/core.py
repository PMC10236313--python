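"""Coordinate conventions, interval data model, and readers/writers.

All coordinates are 0-based half-open (BED convention). One-based formats
are converted at the parsing boundary. Distances between disjoint features
are gap sizes in base pairs; adjacent half-open intervals have distance 0
but do not overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

from intervaltree import IntervalTree

Strand = Literal["+", "-"]

_INF = math.inf


class ParseError(ValueError):
    """A malformed line in an input file; names the offending line number."""


class BoundsError(ValueError):
    """An interval falling outside the genome layout."""


class MissingAnnotationError(ValueError):
    """A required annotation set (genes, peak set) was not supplied."""


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names and lengths defining the coordinate space."""

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in layout")
        for name, length in self.chromosomes:
            if length < 1:
                raise ValueError(f"chromosome {name} has non-positive length {length}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, int]]) -> "GenomeLayout":
        return cls(tuple((str(n), int(l)) for n, l in pairs))

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.chromosomes)

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise BoundsError(f"chromosome {chrom!r} not in layout") from None

    def check(self, interval: "Interval") -> None:
        length = self.length_of(interval.chrom)
        if interval.end > length:
            raise BoundsError(
                f"{interval} exceeds {interval.chrom} length {length}"
            )


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.chrom}:{self.start}-{self.end}")

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, point: int) -> bool:
        return self.chrom == chrom and self.start <= point < self.end

    def distance_to_point(self, chrom: str, point: int) -> float:
        """Gap in bp to a point; 0 if the point lies inside (or adjacent to)
        the half-open interval; +inf across chromosomes."""
        if self.chrom != chrom:
            return _INF
        if point < self.start:
            return self.start - point
        if point >= self.end:
            return point - self.end
        return 0


@dataclass(frozen=True)
class StrandedTag:
    """One aligned sequencing tag."""

    interval: Interval
    strand: Strand

    @property
    def five_prime(self) -> int:
        """5' position of the tag (start on +, end-1 on -)."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def three_prime_end(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start


@dataclass
class Peak:
    """A scored interval from a peak caller, for one mark and condition.

    ``summit`` is an absolute coordinate within [start, end); when the input
    dialect provides no summit it defaults to the interval midpoint.
    """

    interval: Interval
    score: float = 0.0
    summit: Optional[int] = None
    mark: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.score):
            raise ValueError("peak score must be finite")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside {self.interval}"
            )

    @property
    def resolved_summit(self) -> int:
        return self.summit if self.summit is not None else self.interval.midpoint


GeneSource = Literal["refseq_like", "est_like"]


@dataclass(frozen=True)
class GeneModel:
    """A transcription unit as a single stranded interval."""

    name: str
    interval: Interval
    strand: Strand
    source: GeneSource = "refseq_like"

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


@dataclass(frozen=True)
class PromoterRegion:
    """TSS-centered window for a gene, clamped to chromosome bounds."""

    gene: GeneModel
    interval: Interval


def promoter_region(
    gene: GeneModel, layout: GenomeLayout, half_width: int = 1000
) -> PromoterRegion:
    length = layout.length_of(gene.interval.chrom)
    start = max(0, gene.tss - half_width)
    end = min(length, gene.tss + half_width)
    return PromoterRegion(gene, Interval(gene.interval.chrom, start, end))


# ---------------------------------------------------------------------------
# Interval indexing


class IntervalIndex:
    """Per-chromosome interval tree for bulk half-open overlap queries."""

    def __init__(self, intervals: Iterable[Interval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for iv in intervals:
            self.add(iv)

    def add(self, iv: Interval) -> None:
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)

    def overlaps(self, query: Interval) -> bool:
        tree = self._trees.get(query.chrom)
        return bool(tree is not None and tree.overlaps(query.start, query.end))

    def hits(self, query: Interval) -> list[Interval]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return sorted(h.data for h in tree.overlap(query.start, query.end))


def overlaps_any(query: Interval, features: Sequence[Interval] | IntervalIndex) -> bool:
    """True iff some feature shares at least one bp with ``query``."""
    if isinstance(features, IntervalIndex):
        return features.overlaps(query)
    return any(query.overlaps(f) for f in features)


def nearest_tss_distance(
    query: Interval,
    genes: Sequence[GeneModel],
    source_filter: Optional[GeneSource] = None,
) -> float:
    """Minimum bp distance from ``query`` to any gene TSS point.

    0 when a TSS lies within the query; +inf when no gene shares the
    query's chromosome after filtering.
    """
    if not genes:
        raise MissingAnnotationError("nearest_tss_distance: empty gene list")
    best = _INF
    for g in genes:
        if source_filter is not None and g.source != source_filter:
            continue
        d = query.distance_to_point(g.interval.chrom, g.tss)
        if d < best:
            best = d
    return best


# ---------------------------------------------------------------------------
# Readers / writers

PeakFormat = Literal["bed3", "bed6", "narrowpeak"]


def read_chrom_sizes(path: str | Path) -> GenomeLayout:
    pairs = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{i}: expected 2 columns")
        try:
            pairs.append((fields[0], int(fields[1])))
        except ValueError:
            raise ParseError(f"{path}:{i}: non-integer length {fields[1]!r}") from None
    return GenomeLayout.from_pairs(pairs)


def _parse_peak_line(
    fields: list[str], fmt: PeakFormat, where: str
) -> Peak:
    try:
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    except (IndexError, ValueError):
        raise ParseError(f"{where}: malformed coordinates") from None
    if start >= end or start < 0:
        raise ParseError(f"{where}: invalid interval [{start},{end})")
    iv = Interval(chrom, start, end)
    score = 0.0
    summit: Optional[int] = None
    if fmt in ("bed6", "narrowpeak") and len(fields) > 4 and fields[4] not in (".", ""):
        try:
            score = float(fields[4])
        except ValueError:
            raise ParseError(f"{where}: non-numeric score {fields[4]!r}") from None
    if fmt == "narrowpeak":
        if len(fields) < 10:
            raise ParseError(f"{where}: narrowPeak requires 10 columns")
        try:
            offset = int(fields[9])
        except ValueError:
            raise ParseError(f"{where}: non-integer summit offset") from None
        if offset >= 0:
            summit = start + offset
            if summit >= end:
                raise ParseError(f"{where}: summit offset {offset} outside peak")
    if summit is None:
        summit = iv.midpoint
    return Peak(iv, score=score, summit=summit)


def read_intervals(
    path: str | Path,
    format: PeakFormat = "bed6",
    layout: Optional[GenomeLayout] = None,
    mark: str = "",
    condition: str = "",
) -> list[Peak]:
    """Read a peak file in BED3/BED6/narrowPeak dialect, in file order.

    Scores default to 0 when absent; summits to the narrowPeak summit-offset
    column when present, else the interval midpoint. With a bound ``layout``
    out-of-bounds intervals raise :class:`BoundsError`.
    """
    peaks: list[Peak] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        peak = _parse_peak_line(line.rstrip("\n").split("\t"), format, f"{path}:{i}")
        if layout is not None:
            layout.check(peak.interval)
        peak.mark = mark
        peak.condition = condition
        peaks.append(peak)
    return peaks


def write_bed6(
    path: str | Path,
    records: Iterable[tuple[Interval, str, float, str]],
) -> None:
    """Write (interval, name, score, strand) records as BED6."""
    with open(path, "w") as fh:
        for iv, name, score, strand in records:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score:g}\t{strand}\n"
            )


def read_bed6(path: str | Path) -> list[tuple[Interval, str, float, str]]:
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(f"{path}:{i}: expected 6 columns")
        out.append((Interval(f[0], int(f[1]), int(f[2])), f[3], float(f[4]), f[5]))
    return out


def read_gene_table(
    path: str | Path, source: GeneSource = "refseq_like"
) -> list[GeneModel]:
    """Read a refFlat-style gene table.

    Expected columns: geneName, name, chrom, strand, txStart, txEnd
    (any further refFlat columns are ignored). Transcription units are
    single intervals; exon structure is out of scope.
    """
    genes: list[GeneModel] = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) < 6:
            raise ParseError(f"{path}:{i}: refFlat-style table needs 6+ columns")
        strand = f[3]
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{i}: bad strand {strand!r}")
        genes.append(
            GeneModel(
                name=f[0],
                interval=Interval(f[2], int(f[4]), int(f[5])),
                strand=strand,  # type: ignore[arg-type]
                source=source,
            )
        )
    return genes


def write_gene_table(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(
                f"{g.name}\t{g.name}\t{g.interval.chrom}\t{g.strand}"
                f"\t{g.interval.start}\t{g.interval.end}\n"
            )
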