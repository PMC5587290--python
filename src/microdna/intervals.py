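"""Genomic interval primitives and overlap indexes.

All coordinates are 0-based half-open throughout the package; conversion to
and from 1-based file formats happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from intervaltree import IntervalTree


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"interval end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.start < 0:
            raise ValueError(f"negative start: {self.chrom}:{self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def merge_intervals(
    intervals: Iterable[tuple[int, int]],
) -> list[tuple[int, int]]:
    """Merge intervals that overlap by >= 1 bp (touching intervals stay apart)."""
    ivs = sorted(intervals)
    merged: list[list[int]] = []
    for s, e in ivs:
        if merged and s < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


class IntervalIndex:
    """Overlap-queryable interval collection.

    Keeps the raw (possibly named, possibly overlapping) intervals in an
    interval tree per chromosome for identity queries, plus merged sorted
    arrays per chromosome for fast vectorized boolean overlap tests.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self._trees: dict[str, IntervalTree] = {}
        self._raw: list[GenomicInterval] = []
        for iv in intervals:
            self._raw.append(iv)
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, iv
            )
        self._merged: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, tree in self._trees.items():
            pairs = merge_intervals((iv.begin, iv.end) for iv in tree)
            starts = np.array([p[0] for p in pairs], dtype=np.int64)
            ends = np.array([p[1] for p in pairs], dtype=np.int64)
            self._merged[chrom] = (starts, ends)

    def __len__(self) -> int:
        return len(self._raw)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._raw)

    @property
    def chroms(self) -> set[str]:
        return set(self._trees)

    def overlaps_any(self, chrom: str, start: int, end: int) -> bool:
        if chrom not in self._merged:
            return False
        starts, ends = self._merged[chrom]
        i = int(np.searchsorted(starts, end, side="left"))
        return i > 0 and ends[i - 1] > start

    def overlaps_any_vec(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        """Boolean array: does each [start, end) overlap any interval on chrom."""
        if chrom not in self._merged:
            return np.zeros(len(starts), dtype=bool)
        mstarts, mends = self._merged[chrom]
        idx = np.searchsorted(mstarts, ends, side="left")
        out = np.zeros(len(starts), dtype=bool)
        nz = idx > 0
        out[nz] = mends[idx[nz] - 1] > starts[nz]
        return out

    def overlapping(self, chrom: str, start: int, end: int) -> list[GenomicInterval]:
        if chrom not in self._trees:
            return []
        return sorted(
            (hit.data for hit in self._trees[chrom].overlap(start, end)),
            key=lambda iv: (iv.start, iv.end, iv.name),
        )

    def covered_bp(self) -> int:
        return sum(
            int(np.sum(ends - starts)) for starts, ends in self._merged.values()
        )
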