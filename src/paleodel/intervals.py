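"""Genomic interval sets.

All coordinates in this package are 0-based half-open ``[start, end)``,
the BED convention.  VCF and GFF3 positions are converted on read.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

__all__ = ["GenomeIntervalSet"]


class GenomeIntervalSet:
    """Per-chromosome sets of sorted, strandless, half-open intervals.

    Intervals may carry an optional string label (used for provenance
    flags on deletion calls and for category names on annotation
    partitions).  After :meth:`merge` intervals within a chromosome are
    pairwise disjoint and sorted by start.
    """

    def __init__(self) -> None:
        self._ivals: dict[str, list[list]] = {}  # chrom -> [[start, end, label], ...]
        self._sorted = True

    # -- construction ---------------------------------------------------

    @classmethod
    def from_records(
        cls, records: Iterable[tuple]
    ) -> "GenomeIntervalSet":
        """Build from ``(chrom, start, end)`` or ``(chrom, start, end, label)`` tuples."""
        out = cls()
        for rec in records:
            out.add(*rec)
        return out

    @classmethod
    def from_bool(cls, chrom: str, flags: np.ndarray) -> "GenomeIntervalSet":
        """Intervals covering the True runs of a boolean site array."""
        out = cls()
        flags = np.asarray(flags, dtype=bool)
        if flags.size == 0:
            return out
        padded = np.concatenate([[False], flags, [False]])
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            out.add(chrom, int(s), int(e))
        return out

    def add(self, chrom: str, start: int, end: int, label: str | None = None) -> None:
        if start < 0 or start >= end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end} (need 0 <= start < end)")
        self._ivals.setdefault(chrom, []).append([int(start), int(end), label])
        self._sorted = False

    # -- queries --------------------------------------------------------

    def chromosomes(self) -> list[str]:
        return sorted(self._ivals)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        self._ensure_sorted()
        return [(s, e) for s, e, _ in self._ivals.get(chrom, [])]

    def records(self) -> Iterator[tuple[str, int, int, str | None]]:
        self._ensure_sorted()
        for chrom in self.chromosomes():
            for s, e, lab in self._ivals[chrom]:
                yield chrom, s, e, lab

    def __iter__(self) -> Iterator[tuple[str, int, int]]:
        for chrom, s, e, _ in self.records():
            yield chrom, s, e

    def __len__(self) -> int:
        return sum(len(v) for v in self._ivals.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeIntervalSet):
            return NotImplemented
        return [(c, s, e) for c, s, e in self] == [(c, s, e) for c, s, e in other]

    def __repr__(self) -> str:
        return f"GenomeIntervalSet({len(self)} intervals on {len(self._ivals)} chromosomes)"

    def total_length(self, chrom: str | None = None) -> int:
        chroms = [chrom] if chrom is not None else list(self._ivals)
        return sum(e - s for c in chroms for s, e, _ in self._ivals.get(c, []))

    def covers(self, chrom: str, start: int, end: int) -> bool:
        """True iff every site of ``[start, end)`` lies inside the set.

        An empty span is vacuously covered.
        """
        if start >= end:
            return True
        self._ensure_sorted()
        pos = start
        for s, e, _ in self._ivals.get(chrom, []):
            if s > pos:
                return False
            if e > pos:
                pos = e
            if pos >= end:
                return True
        return pos >= end

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff any site of ``[start, end)`` lies inside the set."""
        self._ensure_sorted()
        for s, e, _ in self._ivals.get(chrom, []):
            if s >= end:
                return False
            if e > start:
                return True
        return False

    def to_bool(self, chrom: str, length: int) -> np.ndarray:
        """Boolean site array, True where the chromosome is inside the set."""
        flags = np.zeros(length, dtype=bool)
        self._ensure_sorted()
        for s, e, _ in self._ivals.get(chrom, []):
            if s >= length:
                raise ValueError(f"interval {chrom}:{s}-{e} beyond length {length}")
            flags[s : min(e, length)] = True
        return flags

    # -- set algebra ----------------------------------------------------

    def merge(self, gap: int = 0, combine_labels: bool = False) -> "GenomeIntervalSet":
        """Union intervals whose separation ``start2 - end1`` is <= ``gap``.

        ``gap=0`` unions overlapping and book-ended intervals (bedtools
        ``merge`` default); positive ``gap`` reproduces ``merge -d gap``.
        With ``combine_labels`` the merged interval's label is the
        comma-joined sorted union of constituent labels.
        """
        out = GenomeIntervalSet()
        self._ensure_sorted()
        for chrom in self.chromosomes():
            cur = None
            labels: set[str] = set()
            for s, e, lab in self._ivals[chrom]:
                if cur is None:
                    cur = [s, e]
                    labels = {lab} if lab else set()
                elif s - cur[1] <= gap:
                    cur[1] = max(cur[1], e)
                    if lab:
                        labels.add(lab)
                else:
                    out.add(chrom, cur[0], cur[1], ",".join(sorted(labels)) if combine_labels and labels else None)
                    cur = [s, e]
                    labels = {lab} if lab else set()
            if cur is not None:
                out.add(chrom, cur[0], cur[1], ",".join(sorted(labels)) if combine_labels and labels else None)
        return out

    def complement(self, chrom_lengths: dict[str, int]) -> "GenomeIntervalSet":
        """Complement with respect to whole chromosomes (merged first)."""
        merged = self.merge(0)
        out = GenomeIntervalSet()
        for chrom, length in chrom_lengths.items():
            pos = 0
            for s, e in merged.intervals(chrom):
                if s > pos:
                    out.add(chrom, pos, min(s, length))
                pos = max(pos, e)
            if pos < length:
                out.add(chrom, pos, length)
        return out

    def intersect(self, other: "GenomeIntervalSet") -> "GenomeIntervalSet":
        a, b = self.merge(0), other.merge(0)
        out = GenomeIntervalSet()
        for chrom in a.chromosomes():
            bi = b.intervals(chrom)
            j = 0
            for s, e in a.intervals(chrom):
                while j < len(bi) and bi[j][1] <= s:
                    j += 1
                k = j
                while k < len(bi) and bi[k][0] < e:
                    out.add(chrom, max(s, bi[k][0]), min(e, bi[k][1]))
                    k += 1
        return out

    # -- internals ------------------------------------------------------

    def _ensure_sorted(self) -> None:
        if not self._sorted:
            for chrom in self._ivals:
                self._ivals[chrom].sort(key=lambda r: (r[0], r[1]))
            self._sorted = True
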