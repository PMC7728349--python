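"""Genomic interval algebra on 0-based half-open coordinates.

All downstream peak analyses (replicate consensus, co-occupancy, chromatin
states) run on :class:`IntervalSet`, a per-chromosome collection of sorted,
disjoint, non-adjacent intervals in the BED convention (start inclusive,
end exclusive). The algebra is deliberately small: normalization, set
intersection, width filtering and overlap counting — exactly what a
peak-colocalization analysis needs.

Conventions
-----------
* Coordinates are 0-based half-open, so an interval of width 1 is
  ``(start, start + 1)`` and book-ended intervals (one's end equals the
  other's start) share no base.
* Strand is ignored: peak calls are unstranded.
* Chromosome names are normalized to the ``chr``-prefixed dialect
  (``"1"`` becomes ``"chr1"``); sets with chromosomes absent from the
  other set simply contribute zero overlaps.
* ``normalize`` merges overlapping *and* book-ended intervals, matching
  the reduce semantics of the common ranges libraries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Sequence, Tuple

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "MalformedIntervalError",
    "NotNormalizedError",
    "normalize",
    "intersect",
    "filter_min_width",
    "count_overlaps",
    "overlapping_subset",
    "normalize_chrom_name",
]


class MalformedIntervalError(ValueError):
    """An interval violates ``start >= 0`` or ``end > start``."""


class NotNormalizedError(ValueError):
    """A set-algebra operation received a non-normalized IntervalSet."""


def normalize_chrom_name(chrom: str) -> str:
    """Map chromosome names to the canonical ``chr``-prefixed dialect."""
    chrom = str(chrom).strip()
    if not chrom:
        raise MalformedIntervalError("empty chromosome name")
    if chrom.lower().startswith("chr"):
        return "chr" + chrom[3:]
    return "chr" + chrom


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic region.

    Attributes
    ----------
    chrom : str
        Chromosome name (canonicalized to the ``chr`` dialect).
    start : int
        0-based inclusive start, ``>= 0``.
    end : int
        0-based exclusive end, ``> start``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom_name(self.chrom))
        object.__setattr__(self, "start", int(self.start))
        object.__setattr__(self, "end", int(self.end))
        if self.start < 0:
            raise MalformedIntervalError(f"start < 0: {self!r:.80s}")
        if self.end <= self.start:
            raise MalformedIntervalError(
                f"end <= start in ({self.chrom}, {self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Per-chromosome sorted interval arrays with a normalized flag.

    Internally each chromosome holds two parallel int64 arrays of starts
    and ends. When ``normalized`` is True the intervals on every
    chromosome are sorted by start, pairwise disjoint and non-adjacent.
    Construct via :func:`normalize` (the usual path) or
    :meth:`from_arrays` for already-clean data.
    """

    def __init__(
        self,
        data: Mapping[str, Tuple[np.ndarray, np.ndarray]] | None = None,
        *,
        normalized: bool = False,
    ) -> None:
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
        if data:
            for chrom in sorted(data):
                starts, ends = data[chrom]
                starts = np.asarray(starts, dtype=np.int64)
                ends = np.asarray(ends, dtype=np.int64)
                if starts.shape != ends.shape:
                    raise MalformedIntervalError("starts/ends length mismatch")
                if starts.size:
                    self._data[normalize_chrom_name(chrom)] = (starts, ends)
        self.normalized = bool(normalized)

    # -- construction ----------------------------------------------------

    @classmethod
    def from_arrays(
        cls, data: Mapping[str, Tuple[np.ndarray, np.ndarray]], *, normalized: bool
    ) -> "IntervalSet":
        return cls(data, normalized=normalized)

    # -- basic protocol --------------------------------------------------

    def __len__(self) -> int:
        return sum(starts.size for starts, _ in self._data.values())

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self.chromosomes:
            starts, ends = self._data[chrom]
            for s, e in zip(starts.tolist(), ends.tolist()):
                yield GenomicInterval(chrom, s, e)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if self.chromosomes != other.chromosomes:
            return False
        return all(
            np.array_equal(self._data[c][0], other._data[c][0])
            and np.array_equal(self._data[c][1], other._data[c][1])
            for c in self.chromosomes
        )

    def __repr__(self) -> str:
        return (
            f"IntervalSet({len(self)} intervals on {len(self._data)} "
            f"chromosomes, normalized={self.normalized})"
        )

    @property
    def chromosomes(self) -> List[str]:
        return sorted(self._data)

    def arrays(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for one chromosome; empty arrays if absent."""
        empty = np.empty(0, dtype=np.int64)
        return self._data.get(normalize_chrom_name(chrom), (empty, empty))

    def total_width(self) -> int:
        """Total number of covered bases (only meaningful when normalized)."""
        return int(
            sum((ends - starts).sum() for starts, ends in self._data.values())
        )

    def to_intervals(self) -> List[GenomicInterval]:
        return list(self)


def _require_normalized(*sets: IntervalSet) -> None:
    for s in sets:
        if not isinstance(s, IntervalSet):
            raise TypeError(f"expected IntervalSet, got {type(s).__name__}")
        if not s.normalized:
            raise NotNormalizedError(
                "operation requires a normalized IntervalSet; call normalize()"
            )


def normalize(
    intervals: Iterable[GenomicInterval | Tuple[str, int, int]],
) -> IntervalSet:
    """Sort and merge intervals into a normalized :class:`IntervalSet`.

    Overlapping and book-ended intervals are merged, so the output is
    sorted, pairwise disjoint and non-adjacent while covering exactly the
    same bases as the input.

    Raises
    ------
    MalformedIntervalError
        If any interval has ``end <= start`` or ``start < 0``.
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        if not isinstance(iv, GenomicInterval):
            iv = GenomicInterval(*iv)
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))

    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom, pairs in by_chrom.items():
        pairs.sort()
        merged_starts: List[int] = []
        merged_ends: List[int] = []
        for s, e in pairs:
            # merge book-ended runs too: s == previous end coalesces
            if merged_ends and s <= merged_ends[-1]:
                if e > merged_ends[-1]:
                    merged_ends[-1] = e
            else:
                merged_starts.append(s)
                merged_ends.append(e)
        data[chrom] = (
            np.asarray(merged_starts, dtype=np.int64),
            np.asarray(merged_ends, dtype=np.int64),
        )
    return IntervalSet(data, normalized=True)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases covered by both sets, as a normalized IntervalSet.

    Commutative and associative on covered-base sets;
    ``intersect(a, a) == a``. Chromosomes present in only one set
    contribute nothing.
    """
    _require_normalized(a, b)
    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in a.chromosomes:
        a_starts, a_ends = a.arrays(chrom)
        b_starts, b_ends = b.arrays(chrom)
        if not b_starts.size:
            continue
        out_s: List[int] = []
        out_e: List[int] = []
        i = j = 0
        na, nb = a_starts.size, b_starts.size
        while i < na and j < nb:
            lo = max(a_starts[i], b_starts[j])
            hi = min(a_ends[i], b_ends[j])
            if hi > lo:
                out_s.append(int(lo))
                out_e.append(int(hi))
            # advance whichever interval ends first
            if a_ends[i] <= b_ends[j]:
                i += 1
            else:
                j += 1
        if out_s:
            data[chrom] = (
                np.asarray(out_s, dtype=np.int64),
                np.asarray(out_e, dtype=np.int64),
            )
    # pieces from disjoint inputs are already sorted/disjoint, but two
    # adjacent output pieces can be book-ended (split by an input gap on
    # the other set is impossible; both sets cover the junction base's
    # flanks only if one input had book-ends, which normalization forbids)
    return IntervalSet(data, normalized=True)


def filter_min_width(s: IntervalSet, min_width: int) -> IntervalSet:
    """Drop intervals narrower than ``min_width`` bases.

    ``min_width=1`` is the identity on a normalized set. Used with the
    default consensus threshold of 5 bp to discard sliver regions left
    by replicate intersection.
    """
    _require_normalized(s)
    min_width = int(min_width)
    if min_width < 1:
        raise ValueError(f"min_width must be >= 1, got {min_width}")
    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in s.chromosomes:
        starts, ends = s.arrays(chrom)
        keep = (ends - starts) >= min_width
        if keep.any():
            data[chrom] = (starts[keep], ends[keep])
    return IntervalSet(data, normalized=True)


def count_overlaps(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-query-interval count of overlapping subject intervals.

    Overlap means sharing at least one base under half-open semantics,
    so book-ended pairs do not count. Returns one int per query interval
    in chromosome-sorted iteration order (the order of ``iter(query)``).
    """
    _require_normalized(query, subject)
    chunks: List[np.ndarray] = []
    for chrom in query.chromosomes:
        q_starts, q_ends = query.arrays(chrom)
        s_starts, s_ends = subject.arrays(chrom)
        if not s_starts.size:
            chunks.append(np.zeros(q_starts.size, dtype=np.int64))
            continue
        # subject is sorted and disjoint: intervals overlapping [qs, qe)
        # are exactly those with start < qe and end > qs
        hi = np.searchsorted(s_starts, q_ends, side="left")
        lo = np.searchsorted(s_ends, q_starts, side="right")
        chunks.append(hi - lo)
    if not chunks:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(chunks)


def overlapping_subset(query: IntervalSet, subject: IntervalSet) -> IntervalSet:
    """Query intervals overlapping >= 1 subject interval, kept once each.

    Intervals retain their original coordinates regardless of how many
    subject intervals they touch (each query peak is reported uniquely).
    """
    _require_normalized(query, subject)
    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    for chrom in query.chromosomes:
        q_starts, q_ends = query.arrays(chrom)
        s_starts, s_ends = subject.arrays(chrom)
        if not s_starts.size:
            continue
        hi = np.searchsorted(s_starts, q_ends, side="left")
        lo = np.searchsorted(s_ends, q_starts, side="right")
        keep = (hi - lo) > 0
        if keep.any():
            data[chrom] = (q_starts[keep], q_ends[keep])
    return IntervalSet(data, normalized=True)
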