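"""Genomic interval primitives shared by every other module.

Coordinates follow the GFF3 convention used by all external files: 1-based,
inclusive on both ends.  All set arithmetic (merging, intersection, base
counting) happens on that closed-interval representation so interval lengths
are preserved at every interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = ("+", "-", ".")


class IntervalError(ValueError):
    """Raised when an interval violates the coordinate invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed 1-based interval on one sequence.

    Parameters
    ----------
    seq_id : str
        Identifier of the chromosome / scaffold.
    start, end : int
        1-based inclusive coordinates, ``1 <= start <= end``.
    strand : str
        One of ``+``, ``-`` or ``.`` (unstranded; permitted only for
        expression coverage spans).
    """

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise IntervalError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise IntervalError(
                f"end ({self.end}) must be >= start ({self.start})"
            )
        if self.strand not in VALID_STRANDS:
            raise IntervalError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """Whether the two intervals share at least one base (same seq_id)."""
        return (
            self.seq_id == other.seq_id
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersection_length(self, other: "GenomicInterval") -> int:
        if self.seq_id != other.seq_id:
            return 0
        lo = max(self.start, other.start)
        hi = min(self.end, other.end)
        return max(0, hi - lo + 1)

    def shift(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(
            self.seq_id, self.start + offset, self.end + offset, self.strand
        )


def merge_intervals(
    intervals: Iterable[GenomicInterval],
) -> list[GenomicInterval]:
    """Collapse an arbitrary interval collection into a sorted, disjoint union.

    Strand information is discarded (the union is a base set); intervals on
    different seq_ids are merged independently.  Adjacent-but-not-overlapping
    intervals (end + 1 == next start) are fused, since they cover a contiguous
    base run.
    """
    by_seq: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_seq.setdefault(iv.seq_id, []).append(iv)
    merged: list[GenomicInterval] = []
    for seq_id in sorted(by_seq):
        ivs = sorted(by_seq[seq_id], key=lambda i: (i.start, i.end))
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end + 1:
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(seq_id, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(seq_id, cur_start, cur_end))
    return merged


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct genome bases covered by the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def intersection_bases(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> int:
    """Bases covered by both interval collections (after merging each).

    Both sides are merged to sorted disjoint unions first, so a two-pointer
    sweep per seq_id counts each shared base exactly once.
    """
    by_seq_a: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(a):
        by_seq_a.setdefault(iv.seq_id, []).append(iv)
    by_seq_b: dict[str, list[GenomicInterval]] = {}
    for iv in merge_intervals(b):
        by_seq_b.setdefault(iv.seq_id, []).append(iv)
    total = 0
    for seq_id, ivs_a in by_seq_a.items():
        ivs_b = by_seq_b.get(seq_id)
        if not ivs_b:
            continue
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            lo = max(ivs_a[i].start, ivs_b[j].start)
            hi = min(ivs_a[i].end, ivs_b[j].end)
            if hi >= lo:
                total += hi - lo + 1
            if ivs_a[i].end < ivs_b[j].end:
                i += 1
            else:
                j += 1
    return total


class MergedIndex:
    """Pre-merged interval union with bisect-backed window queries.

    Built once per evidence track so that per-model overlap questions cost
    O(log n + hits) instead of re-merging the whole track each time.
    Merged intervals per seq_id are disjoint and sorted, hence both start
    and end arrays are monotone and independently bisectable.
    """

    def __init__(self, intervals: Iterable[GenomicInterval]) -> None:
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        self._total = 0
        for iv in merge_intervals(intervals):
            self._starts.setdefault(iv.seq_id, []).append(iv.start)
            self._ends.setdefault(iv.seq_id, []).append(iv.end)
            self._total += iv.length

    @property
    def total_bases(self) -> int:
        return self._total

    def window_overlap(self, seq_id: str, start: int, end: int) -> int:
        """Bases of the union falling inside [start, end]."""
        import bisect

        starts = self._starts.get(seq_id)
        if not starts:
            return 0
        ends = self._ends[seq_id]
        lo = bisect.bisect_left(ends, start)
        hi = bisect.bisect_right(starts, end)
        total = 0
        for k in range(lo, hi):
            total += min(ends[k], end) - max(starts[k], start) + 1
        return total

    def intersection_bases(self, intervals: Iterable[GenomicInterval]) -> int:
        """Bases shared with a (merged) query interval collection."""
        return sum(
            self.window_overlap(iv.seq_id, iv.start, iv.end)
            for iv in merge_intervals(intervals)
        )


class SpanIndex:
    """Index of arbitrary objects by genomic span, for window retrieval.

    Items may overlap each other; a running prefix-maximum of span ends
    bounds the backward scan so queries stay near O(log n + hits).
    """

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]]) -> None:
        by_key: dict[tuple[str, str], list[tuple[int, int, object]]] = {}
        for span, obj in items:
            by_key.setdefault((span.seq_id, span.strand), []).append(
                (span.start, span.end, obj)
            )
        self._index: dict[tuple[str, str], tuple[list, list, list]] = {}
        for key, triples in by_key.items():
            triples.sort(key=lambda t: (t[0], t[1]))
            starts = [t[0] for t in triples]
            max_end = []
            cur = 0
            for t in triples:
                cur = max(cur, t[1])
                max_end.append(cur)
            self._index[key] = (starts, max_end, triples)

    def window(
        self, seq_id: str, strand: str, start: int, end: int
    ) -> list[object]:
        import bisect

        entry = self._index.get((seq_id, strand))
        if entry is None:
            return []
        starts, max_end, triples = entry
        hi = bisect.bisect_right(starts, end)
        out = []
        k = hi - 1
        while k >= 0 and max_end[k] >= start:
            if triples[k][1] >= start:
                out.append(triples[k][2])
            k -= 1
        out.reverse()
        return out


def intervals_overlap_any(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> bool:
    """True if any interval of *a* shares a base with any interval of *b*."""
    for iv in a:
        for other in b:
            if iv.overlaps(other):
                return True
    return False
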