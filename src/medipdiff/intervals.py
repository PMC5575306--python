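"""Genomic interval primitives.

All coordinates in this package are 0-based half-open ``[start, end)``,
BED-style. GTF input is converted to this convention at the I/O boundary.
Interval collections are kept as plain lists of :class:`GenomicInterval`;
the algebra below (merge, subtract, overlap) operates per chromosome on
sorted coordinate arrays.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Iterable, Mapping, NamedTuple

import numpy as np


class GenomicInterval(NamedTuple):
    """A half-open genomic interval ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def validate_interval(
    iv: GenomicInterval, genome_lengths: Mapping[str, int] | None = None
) -> None:
    """Raise ``ValueError`` if *iv* violates the coordinate invariants."""
    if iv.start < 0:
        raise ValueError(f"negative start in {iv}")
    if iv.end <= iv.start:
        raise ValueError(f"empty or inverted interval {iv}")
    if genome_lengths is not None:
        if iv.chrom not in genome_lengths:
            raise ValueError(f"unknown chromosome {iv.chrom!r}")
        if iv.end > genome_lengths[iv.chrom]:
            raise ValueError(f"{iv} exceeds chromosome length")


def group_by_chrom(
    intervals: Iterable[GenomicInterval],
) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        out[iv.chrom].append(iv)
    return dict(out)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals: sorted, disjoint, with touching intervals fused."""
    merged: list[GenomicInterval] = []
    for chrom in sorted(group_by_chrom(intervals)):
        ivs = sorted(group_by_chrom(intervals)[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def subtract_intervals(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Set difference ``union(a) - union(b)`` as sorted disjoint intervals."""
    a_merged = merge_intervals(a) if a else []
    if not a_merged:
        return []
    b_by_chrom = group_by_chrom(merge_intervals(b) if b else [])
    out: list[GenomicInterval] = []
    for iv in a_merged:
        cuts = b_by_chrom.get(iv.chrom, [])
        pos = iv.start
        for cut in cuts:
            if cut.end <= pos or cut.start >= iv.end:
                continue
            if cut.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, cut.start))
            pos = max(pos, cut.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total genomic footprint in bp of the union of *intervals*."""
    return sum(iv.length for iv in merge_intervals(intervals)) if intervals else 0


def overlap_bp(region: GenomicInterval, intervals: Iterable[GenomicInterval]) -> int:
    """Number of bases of *region* covered by the union of *intervals*."""
    same = [iv for iv in intervals if iv.chrom == region.chrom]
    if not same:
        return 0
    merged = merge_intervals(same)
    starts = np.array([iv.start for iv in merged])
    ends = np.array([iv.end for iv in merged])
    ov = np.minimum(ends, region.end) - np.maximum(starts, region.start)
    return int(np.clip(ov, 0, None).sum())


def clip_interval(iv: GenomicInterval, chrom_length: int) -> GenomicInterval | None:
    """Clip to ``[0, chrom_length)``; ``None`` if nothing remains."""
    s, e = max(0, iv.start), min(chrom_length, iv.end)
    if e <= s:
        return None
    return GenomicInterval(iv.chrom, s, e, iv.strand)
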