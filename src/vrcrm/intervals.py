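"""Genomic interval algebra.

All coordinates are 0-based half-open (BED convention). Strand is carried
but ignored by the algebra; only motif operations interpret it. These
primitives back every downstream stage: cis-hotspot intersection,
enhancer stitching, homotypic-cluster aggregation, and proximity tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

#: distance reported for a query on a chromosome absent from the reference
UNREACHABLE = float("inf")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Sorting key is (chrom, start, end); most operations sort lazily.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = list(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.sorted():
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def total_span(self) -> int:
        """Number of bases covered (union)."""
        return sum(len(iv) for iv in merge_intervals(self, 0))


def merge_intervals(iset: IntervalSet, max_gap: int = 0) -> IntervalSet:
    """Merge intervals whose gap (next.start - prev.end) is <= ``max_gap``.

    The merge test is inclusive at equality, mirroring ROSE stitching where
    peaks separated by exactly the stitch distance are joined. Names, scores
    and strands are dropped from merged output.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be non-negative, got {max_gap}")
    out: list[GenomicInterval] = []
    for chrom, ivs in iset.by_chrom().items():
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start - cur_end <= max_gap:
                cur_end = max(cur_end, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_start, cur_end))
    return IntervalSet(out)


def _intersect_pair(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Base-level intersection of two interval sets (both merged first)."""
    am, bm = merge_intervals(a, 0).by_chrom(), merge_intervals(b, 0).by_chrom()
    out: list[GenomicInterval] = []
    for chrom in sorted(set(am) & set(bm)):
        xs, ys = am[chrom], bm[chrom]
        i = j = 0
        while i < len(xs) and j < len(ys):
            lo = max(xs[i].start, ys[j].start)
            hi = min(xs[i].end, ys[j].end)
            if lo < hi:
                out.append(GenomicInterval(chrom, lo, hi))
            if xs[i].end <= ys[j].end:
                i += 1
            else:
                j += 1
    return IntervalSet(out)


def intersect_multi(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Base-level intersection of all sets, applied pairwise in order.

    Because the semantics are base-level, the result is independent of the
    order in which the sets are given.
    """
    if len(sets) == 0:
        raise ValueError("intersect_multi requires at least one interval set")
    acc = merge_intervals(sets[0], 0)
    for other in sets[1:]:
        acc = _intersect_pair(acc, other)
    return acc


def nearest_distance(
    query: IntervalSet, reference: IntervalSet
) -> np.ndarray:
    """Per-query distance in bp to the nearest reference interval.

    Overlapping intervals are at distance 0; otherwise the count of bases
    strictly between the nearest edges is reported. Queries on chromosomes
    with no reference get :data:`UNREACHABLE` (``inf``). Equidistant
    references tie-break to the leftmost, which does not affect the value.
    """
    ref = reference.by_chrom()
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in ref.items()}
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in ref.items()}
    out = np.empty(len(query), dtype=float)
    for k, iv in enumerate(query):
        if iv.chrom not in ref:
            out[k] = UNREACHABLE
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]
        # gap is 0 on overlap; else distance between nearest edges
        gaps = np.maximum(s - iv.end, iv.start - e)
        out[k] = max(int(gaps.min()), 0)
    return out


@dataclass(frozen=True)
class Cluster:
    """A run of nearby interval instances emitted by :func:`cluster_intervals`."""

    interval: GenomicInterval
    n_members: int


def cluster_intervals(
    instances: IntervalSet, max_gap: int, min_count: int
) -> list[Cluster]:
    """Find maximal runs of instances with consecutive gaps strictly < ``max_gap``.

    Runs holding at least ``min_count`` members are emitted as one interval
    spanning the first member's start to the last member's end. The strict
    inequality mirrors the homotypic-domain criterion of at least three
    motif instances spaced by <75 bp.
    """
    if min_count < 1:
        raise ValueError(f"min_count must be >= 1, got {min_count}")
    out: list[Cluster] = []
    for chrom, ivs in instances.by_chrom().items():
        run: list[GenomicInterval] = [ivs[0]]
        for iv in ivs[1:]:
            if iv.start - run[-1].end < max_gap:
                run.append(iv)
            else:
                if len(run) >= min_count:
                    out.append(_emit(chrom, run))
                run = [iv]
        if len(run) >= min_count:
            out.append(_emit(chrom, run))
    return out


def _emit(chrom: str, run: list[GenomicInterval]) -> Cluster:
    return Cluster(
        GenomicInterval(chrom, run[0].start, max(iv.end for iv in run)),
        n_members=len(run),
    )


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases of ``a`` not covered by ``b`` (base-level complement within a)."""
    bm = merge_intervals(b, 0).by_chrom()
    out: list[GenomicInterval] = []
    for chrom, ivs in merge_intervals(a, 0).by_chrom().items():
        blockers = bm.get(chrom, [])
        for iv in ivs:
            cursor = iv.start
            for bl in blockers:
                if bl.end <= cursor or bl.start >= iv.end:
                    continue
                if bl.start > cursor:
                    out.append(GenomicInterval(chrom, cursor, bl.start))
                cursor = max(cursor, bl.end)
                if cursor >= iv.end:
                    break
            if cursor < iv.end:
                out.append(GenomicInterval(chrom, cursor, iv.end))
    return IntervalSet(out)


def overlaps_any(query: IntervalSet, reference: IntervalSet) -> np.ndarray:
    """Boolean per query: does it share >= 1 bp with any reference interval?"""
    ref = merge_intervals(reference, 0).by_chrom()
    starts = {c: np.array([iv.start for iv in ivs]) for c, ivs in ref.items()}
    ends = {c: np.array([iv.end for iv in ivs]) for c, ivs in ref.items()}
    out = np.zeros(len(query), dtype=bool)
    for k, iv in enumerate(query):
        if iv.chrom not in ref:
            continue
        s, e = starts[iv.chrom], ends[iv.chrom]
        out[k] = bool(np.any((s < iv.end) & (iv.start < e)))
    return out


def make_windows(chrom_sizes: dict[str, int], width: int) -> IntervalSet:
    """Tile each chromosome with fixed-width windows (last partial kept)."""
    if width < 1:
        raise ValueError("window width must be >= 1")
    out = []
    for chrom, size in chrom_sizes.items():
        for s in range(0, size, width):
            out.append(GenomicInterval(chrom, s, min(s + width, size)))
    return IntervalSet(out)
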