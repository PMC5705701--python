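"""Genomic interval primitives shared by every stage of the pipeline.

All coordinates are 0-based half-open internally, whatever the source
dialect was (BED is taken as-is; GTF is converted on read).  The helpers
here are deliberately small: merge, clip, overlap length, and a sparse
per-base score track.  Each one is cross-checked against brute force in
the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional strand."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {sorted(VALID_STRANDS)}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def merge_spans(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) half-open spans on a single sequence.

    Touching spans ([10,20) and [20,30)) are merged, matching the
    collapsed-exon semantics used throughout.
    """
    ordered = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in ordered:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Strand-agnostic union per chromosome; result strand is '.'."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        for s, e in merge_spans(by_chrom[chrom]):
            out.append(GenomicInterval(chrom, s, e, "."))
    return out


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in intervals)


def overlap_length_with_set(
    target: GenomicInterval, elements: Sequence[GenomicInterval]
) -> int:
    """Base pairs of ``target`` covered by the union of ``elements``.

    Elements are merged first so overlapping elements are not counted
    twice.
    """
    spans = [
        (max(target.start, e.start), min(target.end, e.end))
        for e in elements
        if e.chrom == target.chrom and e.start < target.end and target.start < e.end
    ]
    return sum(e - s for s, e in merge_spans(spans))


class ConservationTrack:
    """Sparse per-base conservation scores keyed by (chrom, position).

    Built from bedGraph records; positions absent from the source are
    reported as missing (``None``).  Real tracks (e.g. PhyloP) are dense,
    but the pipeline only ever queries a handful of bases around splice
    sites, so a sparse dict is both sufficient and exact.
    """

    def __init__(self) -> None:
        self._scores: dict[tuple[str, int], float] = {}

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "ConservationTrack":
        track = cls()
        for chrom, start, end, value in records:
            if start >= end:
                raise ValueError(f"bad bedGraph span [{start}, {end})")
            for pos in range(start, end):
                track._scores[(chrom, pos)] = float(value)
        return track

    def set_score(self, chrom: str, pos: int, value: float) -> None:
        self._scores[(chrom, pos)] = float(value)

    def get(self, chrom: str, pos: int) -> float | None:
        return self._scores.get((chrom, pos))

    def __len__(self) -> int:
        return len(self._scores)

    def to_bedgraph_records(self) -> list[tuple[str, int, int, float]]:
        """Single-base records in deterministic order (for round-trips)."""
        return [
            (chrom, pos, pos + 1, val)
            for (chrom, pos), val in sorted(self._scores.items())
        ]


@dataclass
class IntervalIndex:
    """Sorted per-chromosome arrays supporting fast range queries.

    A thin structure used for flank scans (Alu pairing) where
    ``intervaltree`` point queries are slower than a pair of
    ``searchsorted`` calls on ~1e4 features.
    """

    chroms: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    items: dict[str, list] = field(default_factory=dict)

    @classmethod
    def build(cls, intervals: Sequence[GenomicInterval], payloads=None):
        idx = cls()
        if payloads is None:
            payloads = intervals
        order: dict[str, list[int]] = {}
        for i, iv in enumerate(intervals):
            order.setdefault(iv.chrom, []).append(i)
        for chrom, ids in order.items():
            ids.sort(key=lambda i: (intervals[i].start, intervals[i].end))
            starts = np.array([intervals[i].start for i in ids], dtype=np.int64)
            ends = np.array([intervals[i].end for i in ids], dtype=np.int64)
            max_end = np.maximum.accumulate(ends)
            idx.chroms[chrom] = {"starts": starts, "ends": ends, "max_end": max_end}
            idx.items[chrom] = [payloads[i] for i in ids]
        return idx

    def overlapping(self, chrom: str, start: int, end: int) -> list:
        """All payloads whose interval overlaps [start, end) on chrom."""
        if chrom not in self.chroms:
            return []
        arr = self.chroms[chrom]
        hi = int(np.searchsorted(arr["starts"], end, side="left"))
        # max_end is monotone, so indices below lo cannot reach `start`
        lo = int(np.searchsorted(arr["max_end"], start, side="right"))
        out = []
        for i in range(lo, hi):
            if arr["ends"][i] > start:
                out.append(self.items[chrom][i])
        return out
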