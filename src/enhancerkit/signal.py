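"""Tag-level signal processing.

3' extension, deduplication, fixed-width binning, RPM normalization,
anchor (metagene) profiles, and FPKM with the pseudocount floor of
1 read per 10^8 mapped reads per kilobase (0.01 on the FPKM scale).

Tags are held in :class:`Tags`, a per-chromosome column store (numpy
arrays) so that multi-million-tag libraries process in vectorized form;
``StrandedTag`` lists convert losslessly in both directions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .core import BoundsError, GenomeLayout, Interval, ParseError, StrandedTag

Counting = Literal["midpoint", "overlap"]

FPKM_PSEUDOCOUNT = 0.01  # 1 read per 100M mapped reads per kb, on the FPKM scale


@dataclass(frozen=True)
class LibraryStats:
    """Library size used as the RPM/FPKM normalizer."""

    total_mapped: int
    duplication_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.total_mapped < 1:
            raise ValueError("total_mapped must be >= 1")
        if not (0.0 <= self.duplication_rate <= 1.0):
            raise ValueError("duplication_rate must be in [0,1]")


class Tags:
    """Stranded tags stored as per-chromosome (start, end, strand) arrays.

    ``strand`` is stored as int8: +1 for '+', -1 for '-'. Order within a
    chromosome follows insertion order (file order for parsed input).
    """

    def __init__(self, data: Optional[dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = None):
        self._data = data or {}

    # -- construction -------------------------------------------------
    @classmethod
    def from_records(cls, tags: Iterable[StrandedTag]) -> "Tags":
        buckets: dict[str, list[tuple[int, int, int]]] = {}
        for t in tags:
            buckets.setdefault(t.interval.chrom, []).append(
                (t.interval.start, t.interval.end, 1 if t.strand == "+" else -1)
            )
        data = {}
        for chrom, rows in buckets.items():
            arr = np.asarray(rows, dtype=np.int64)
            data[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2].astype(np.int8))
        return cls(data)

    @classmethod
    def coerce(cls, tags: "Tags | Iterable[StrandedTag]") -> "Tags":
        return tags if isinstance(tags, Tags) else cls.from_records(tags)

    def to_records(self) -> list[StrandedTag]:
        out = []
        for chrom in sorted(self._data):
            s, e, st = self._data[chrom]
            for i in range(len(s)):
                out.append(
                    StrandedTag(
                        Interval(chrom, int(s[i]), int(e[i])),
                        "+" if st[i] > 0 else "-",
                    )
                )
        return out

    # -- basic protocol ------------------------------------------------
    def __len__(self) -> int:
        return sum(len(s) for s, _, _ in self._data.values())

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._data.get(
            chrom,
            (
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int64),
                np.empty(0, dtype=np.int8),
            ),
        )

    def stats(self, duplication_rate: float = 0.0) -> LibraryStats:
        return LibraryStats(max(1, len(self)), duplication_rate)


@dataclass
class CoverageTrack:
    """Per-chromosome binned tag counts (or RPM values after normalization)."""

    layout: GenomeLayout
    bin_size: int
    data: dict[str, np.ndarray]
    strand: Literal["+", "-", "both"] = "both"
    unit: Literal["count", "rpm"] = "count"

    def n_bins(self, chrom: str) -> int:
        return -(-self.layout.length_of(chrom) // self.bin_size)

    def vector(self, chrom: str) -> np.ndarray:
        if chrom not in self.data:
            dtype = float if self.unit == "rpm" else np.int64
            return np.zeros(self.n_bins(chrom), dtype=dtype)
        return self.data[chrom]

    def total(self) -> float:
        return float(sum(v.sum() for v in self.data.values()))


@dataclass
class AnchorProfile:
    """Position-wise mean RPM around a set of anchors."""

    bins: np.ndarray
    half_width: int
    bin_size: int
    n_anchors: int

    @property
    def offsets(self) -> np.ndarray:
        return np.arange(-self.half_width, self.half_width, self.bin_size)


# ---------------------------------------------------------------------------
# Operations


def extend_tags(
    tags: Tags | Iterable[StrandedTag], extension: int, layout: GenomeLayout
) -> Tags:
    """Lengthen each tag past its 3' end by ``extension`` bp.

    '+' tags grow at their end coordinate; '-' tags at their start. Results
    are clamped to [0, chromosome length); order is preserved.
    """
    if extension < 0:
        raise ValueError("extension must be >= 0")
    tags = Tags.coerce(tags)
    out = {}
    for chrom in tags.chroms:
        length = layout.length_of(chrom)
        s, e, st = tags.arrays(chrom)
        if len(s) and (s.min() < 0 or e.max() > length):
            raise BoundsError(f"tag outside layout on {chrom}")
        plus = st > 0
        new_s = np.where(plus, s, np.maximum(0, s - extension))
        new_e = np.where(plus, np.minimum(length, e + extension), e)
        out[chrom] = (new_s, new_e, st)
    return Tags(out)


def deduplicate_tags(
    tags: Tags | Iterable[StrandedTag],
) -> tuple[Tags, float]:
    """Retain one tag per (chrom, start, strand) key; report removed/total."""
    tags = Tags.coerce(tags)
    total = len(tags)
    if total == 0:
        return Tags(), 0.0
    out = {}
    kept = 0
    for chrom in tags.chroms:
        s, e, st = tags.arrays(chrom)
        key = np.stack([s, st.astype(np.int64)], axis=1)
        _, idx = np.unique(key, axis=0, return_index=True)
        idx.sort()
        out[chrom] = (s[idx], e[idx], st[idx])
        kept += len(idx)
    return Tags(out), (total - kept) / total


def bin_counts(
    tags: Tags | Iterable[StrandedTag],
    layout: GenomeLayout,
    bin_size: int = 100,
    counting: Counting = "midpoint",
    strand: Literal["+", "-", "both"] = "both",
) -> CoverageTrack:
    """Bin tags into fixed windows.

    Midpoint counting increments exactly one bin per tag (conserving the
    tag total); overlap counting increments every bin a tag intersects.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    tags = Tags.coerce(tags)
    data: dict[str, np.ndarray] = {}
    for chrom in tags.chroms:
        length = layout.length_of(chrom)
        n_bins = -(-length // bin_size)
        s, e, st = tags.arrays(chrom)
        if strand != "both":
            keep = st > 0 if strand == "+" else st < 0
            s, e = s[keep], e[keep]
        vec = np.zeros(n_bins, dtype=np.int64)
        if len(s):
            if counting == "midpoint":
                mids = (s + e) // 2
                np.add.at(vec, np.clip(mids // bin_size, 0, n_bins - 1), 1)
            else:
                first = np.clip(s // bin_size, 0, n_bins - 1)
                last = np.clip((e - 1) // bin_size, 0, n_bins - 1)
                # difference-array accumulation of [first, last] ranges
                diff = np.zeros(n_bins + 1, dtype=np.int64)
                np.add.at(diff, first, 1)
                np.add.at(diff, last + 1, -1)
                vec = np.cumsum(diff[:-1])
        data[chrom] = vec
    return CoverageTrack(layout, bin_size, data, strand=strand, unit="count")


def rpm_normalize(track: CoverageTrack, stats: LibraryStats) -> CoverageTrack:
    """Scale raw bin counts to reads per million mapped reads."""
    factor = 1e6 / stats.total_mapped
    data = {c: v.astype(float) * factor for c, v in track.data.items()}
    return CoverageTrack(
        track.layout, track.bin_size, data, strand=track.strand, unit="rpm"
    )


def anchor_profile(
    track: CoverageTrack,
    anchors: Sequence[tuple[str, int, str]],
    half_width: int = 5000,
) -> AnchorProfile:
    """Average the RPM track position-wise around anchor points.

    Each anchor contributes the bins covering [point - half_width,
    point + half_width); '-' strand anchors are reversed so that the
    profile reads 5'->3'. Anchors truncated by chromosome ends contribute
    only their defined bins (mean taken over contributing anchors).
    """
    if not anchors:
        raise ValueError("anchor_profile requires at least one anchor")
    bs = track.bin_size
    if half_width % bs != 0:
        raise ValueError("half_width must be a multiple of bin_size")
    width = 2 * half_width // bs
    total = np.zeros(width, dtype=float)
    count = np.zeros(width, dtype=int)
    for chrom, point, strand in anchors:
        vec = track.vector(chrom)
        n = len(vec)
        first = (point - half_width) // bs
        window = np.full(width, np.nan)
        lo = max(first, 0)
        hi = min(first + width, n)
        if hi > lo:
            window[lo - first : hi - first] = vec[lo:hi]
        if strand == "-":
            window = window[::-1]
        ok = ~np.isnan(window)
        total[ok] += window[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), 0.0)
    return AnchorProfile(mean, half_width, bs, len(anchors))


def region_fpkm(
    tags_in_region: int, region_length: int, stats: LibraryStats
) -> float:
    """Fragments per kilobase per million mapped reads, pseudocount-floored.

    FPKM = count * 1e9 / (length * total_mapped) + 0.01, where the additive
    0.01 is the FPKM-scale equivalent of 1 read per 100M mapped reads per kb.
    """
    if region_length < 1:
        raise ValueError("region_length must be >= 1")
    return (
        tags_in_region * 1e9 / (region_length * stats.total_mapped)
        + FPKM_PSEUDOCOUNT
    )


def count_tags_in_window(
    tags: Tags, chrom: str, start: int, end: int, strand: Literal["+", "-", "both"] = "both"
) -> int:
    """Count tags whose 5' position lies in [start, end)."""
    s, e, st = tags.arrays(chrom)
    five = np.where(st > 0, s, e - 1)
    keep = (five >= start) & (five < end)
    if strand == "+":
        keep &= st > 0
    elif strand == "-":
        keep &= st < 0
    return int(keep.sum())


def count_tag_midpoints_in_windows(
    tags: Tags, windows: Sequence[Interval]
) -> np.ndarray:
    """Vectorized count of tag midpoints falling in each window."""
    counts = np.zeros(len(windows), dtype=np.int64)
    by_chrom: dict[str, np.ndarray] = {}
    for chrom in tags.chroms:
        s, e, _ = tags.arrays(chrom)
        by_chrom[chrom] = np.sort((s + e) // 2)
    for i, w in enumerate(windows):
        mids = by_chrom.get(w.chrom)
        if mids is None:
            continue
        counts[i] = np.searchsorted(mids, w.end) - np.searchsorted(mids, w.start)
    return counts


# ---------------------------------------------------------------------------
# I/O


def read_tagalign(path: str | Path) -> Tags:
    """Read a tagAlign-style BED: chrom, start, end, [name, score,] strand."""
    buckets: dict[str, list[tuple[int, int, int]]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        f = line.split("\t")
        try:
            chrom, start, end = f[0], int(f[1]), int(f[2])
            strand = f[5] if len(f) >= 6 else f[3]
        except (IndexError, ValueError):
            raise ParseError(f"{path}:{i}: malformed tagAlign line") from None
        if strand not in ("+", "-"):
            raise ParseError(f"{path}:{i}: bad strand {strand!r}")
        if start >= end:
            raise ParseError(f"{path}:{i}: invalid interval")
        buckets.setdefault(chrom, []).append(
            (start, end, 1 if strand == "+" else -1)
        )
    data = {}
    for chrom, rows in buckets.items():
        arr = np.asarray(rows, dtype=np.int64)
        data[chrom] = (arr[:, 0], arr[:, 1], arr[:, 2].astype(np.int8))
    return Tags(data)


def write_tagalign(path: str | Path, tags: Tags) -> None:
    import pandas as pd

    frames = []
    for chrom in tags.chroms:
        s, e, st = tags.arrays(chrom)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": s,
                    "end": e,
                    "name": "N",
                    "score": 0,
                    "strand": np.where(st > 0, "+", "-"),
                }
            )
        )
    if frames:
        pd.concat(frames).to_csv(path, sep="\t", header=False, index=False)
    else:
        Path(path).write_text("")


def write_bedgraph(path: str | Path, track: CoverageTrack) -> None:
    """Write non-zero bins as bedGraph."""
    bs = track.bin_size
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            vec = track.data[chrom]
            length = track.layout.length_of(chrom)
            nz = np.nonzero(vec)[0]
            for b in nz:
                fh.write(
                    f"{chrom}\t{b * bs}\t{min((b + 1) * bs, length)}\t{vec[b]:g}\n"
                )


def write_profile_tsv(path: str | Path, profile: AnchorProfile) -> None:
    with open(path, "w") as fh:
        fh.write("offset_bp\tmean_rpm\n")
        for off, val in zip(profile.offsets, profile.bins):
            fh.write(f"{off}\t{val:.6g}\n")
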