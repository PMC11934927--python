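"""Interval algebra against brute-force oracles and boundary rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vrcrm.intervals import (
    UNREACHABLE,
    GenomicInterval,
    IntervalSet,
    cluster_intervals,
    intersect_multi,
    make_windows,
    merge_intervals,
    nearest_distance,
    overlaps_any,
    subtract,
)

from conftest import random_interval_set


def iv(s, e, chrom="chr1", **kw):
    return GenomicInterval(chrom, s, e, **kw)


# ---------------------------------------------------------------- oracles


def merge_oracle(ivs, gap):
    """Union closure by repeated pairwise joining, O(n^2) per pass."""
    items = [(i.chrom, i.start, i.end) for i in ivs]
    changed = True
    while changed:
        changed = False
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                ca, sa, ea = items[a]
                cb, sb, eb = items[b]
                if ca == cb and max(sa, sb) - min(ea, eb) <= gap:
                    items[a] = (ca, min(sa, sb), max(ea, eb))
                    del items[b]
                    changed = True
                    break
            if changed:
                break
    return sorted(items)


def covered_bases(iset):
    return {(i.chrom, b) for i in iset for b in range(i.start, i.end)}


def cluster_oracle(ivs, max_gap, min_count):
    """Quadratic run finder over sorted instances."""
    out = []
    by_chrom = {}
    for i in sorted(ivs, key=lambda x: (x.chrom, x.start, x.end)):
        by_chrom.setdefault(i.chrom, []).append(i)
    for chrom, items in by_chrom.items():
        run = [items[0]]
        for x in items[1:]:
            if x.start - run[-1].end < max_gap:
                run.append(x)
            else:
                if len(run) >= min_count:
                    out.append((chrom, run[0].start, max(r.end for r in run), len(run)))
                run = [x]
        if len(run) >= min_count:
            out.append((chrom, run[0].start, max(r.end for r in run), len(run)))
    return sorted(out)


# ----------------------------------------------------------------- merge


@pytest.mark.parametrize(
    "intervals,gap,expected",
    [
        ([], 0, []),
        ([(0, 10), (8, 20), (30, 40)], 0, [(0, 20), (30, 40)]),
        ([(0, 10), (20, 25)], 12, [(0, 25)]),  # gap 10 <= 12, merged
        ([(0, 10), (22, 25)], 12, [(0, 25)]),  # gap exactly 12 merges (inclusive)
        ([(0, 10), (23, 25)], 12, [(0, 10), (23, 25)]),  # gap 13 stays split
    ],
)
def test_merge_examples(intervals, gap, expected):
    got = merge_intervals(IntervalSet([iv(s, e) for s, e in intervals]), gap)
    assert [(i.start, i.end) for i in got] == expected


def test_merge_rejects_negative_gap():
    with pytest.raises(ValueError):
        merge_intervals(IntervalSet([iv(0, 5)]), -1)


def test_merge_matches_union_closure_oracle(rng):
    for _ in range(20):
        s = random_interval_set(rng, 40)
        gap = int(rng.integers(0, 50))
        got = [(i.chrom, i.start, i.end) for i in merge_intervals(s, gap)]
        assert sorted(got) == merge_oracle(s, gap)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(0, 500), st.integers(1, 60)), min_size=1, max_size=30
    ),
    st.integers(0, 40),
)
def test_merge_idempotent(pairs, gap):
    s = IntervalSet([iv(a, a + b) for a, b in pairs])
    once = merge_intervals(s, gap)
    twice = merge_intervals(once, gap)
    assert [(i.start, i.end) for i in once] == [(i.start, i.end) for i in twice]


# ------------------------------------------------------------- intersect


def test_intersect_identity_and_examples():
    s = IntervalSet([iv(0, 10)])
    assert [(i.start, i.end) for i in intersect_multi([s])] == [(0, 10)]
    got = intersect_multi([IntervalSet([iv(0, 10)]), IntervalSet([iv(5, 15)])])
    assert [(i.start, i.end) for i in got] == [(5, 10)]
    empty = intersect_multi([IntervalSet([iv(0, 10)]), IntervalSet([iv(20, 30)])])
    assert len(empty) == 0


def test_intersect_requires_nonempty_list():
    with pytest.raises(ValueError):
        intersect_multi([])


def test_intersect_matches_per_base_oracle_and_order_invariant(rng):
    for _ in range(10):
        sets = [random_interval_set(rng, 15, max_pos=3000) for _ in range(3)]
        got = intersect_multi(sets)
        expected = covered_bases(sets[0])
        for s in sets[1:]:
            expected &= covered_bases(s)
        assert covered_bases(got) == expected
        reordered = intersect_multi(sets[::-1])
        assert covered_bases(reordered) == expected


# --------------------------------------------------------------- nearest


def test_nearest_distance_rules():
    refs = IntervalSet([iv(0, 10), iv(150, 160)])
    inside = IntervalSet([iv(3, 5)])
    assert nearest_distance(inside, refs)[0] == 0
    between = IntervalSet([iv(100, 101)])
    assert nearest_distance(between, refs)[0] == 49
    off_chrom = IntervalSet([iv(0, 5, chrom="chrX")])
    assert nearest_distance(off_chrom, refs)[0] == UNREACHABLE


def test_nearest_distance_symmetric_on_overlap():
    a = IntervalSet([iv(100, 200)])
    b = IntervalSet([iv(150, 250)])
    assert nearest_distance(a, b)[0] == 0
    assert nearest_distance(b, a)[0] == 0


def test_nearest_distance_exhaustive_oracle(rng):
    refs = random_interval_set(rng, 30, max_pos=5000)
    queries = random_interval_set(rng, 30, max_pos=5000)
    got = nearest_distance(queries, refs)
    for q, d in zip(queries, got):
        gaps = [
            max(r.start - q.end, q.start - r.end, 0)
            for r in refs
            if r.chrom == q.chrom
        ]
        assert d == (min(gaps) if gaps else UNREACHABLE)


# --------------------------------------------------------------- cluster


def test_cluster_examples_and_boundaries():
    # two instances can never satisfy min_count=3
    two = IntervalSet([iv(0, 25), iv(50, 75)])
    assert cluster_intervals(two, 75, 3) == []

    # gaps 25 and 45, both < 75: one cluster spanning [0, 145)
    three = IntervalSet([iv(0, 25), iv(50, 75), iv(120, 145)])
    got = cluster_intervals(three, 75, 3)
    assert len(got) == 1
    assert (got[0].interval.start, got[0].interval.end, got[0].n_members) == (0, 145, 3)

    # a gap of exactly 75 breaks the run (strict inequality)
    boundary = IntervalSet([iv(0, 25), iv(100, 125), iv(200, 225)])
    assert cluster_intervals(boundary, 75, 3) == []


def test_cluster_rejects_min_count_below_one():
    with pytest.raises(ValueError):
        cluster_intervals(IntervalSet([iv(0, 5)]), 75, 0)


def test_cluster_matches_quadratic_oracle(rng):
    for _ in range(10):
        s = random_interval_set(rng, 200, max_pos=20_000, max_len=30)
        # clustering operates on non-overlapping instances
        s = merge_intervals(s, 0)
        gap = int(rng.integers(10, 200))
        k = int(rng.integers(2, 5))
        got = [
            (c.interval.chrom, c.interval.start, c.interval.end, c.n_members)
            for c in cluster_intervals(s, gap, k)
        ]
        assert sorted(got) == cluster_oracle(s, gap, k)


# ------------------------------------------------------------- utilities


def test_subtract_and_windows_and_overlaps():
    a = IntervalSet([iv(0, 100)])
    b = IntervalSet([iv(20, 30), iv(50, 60)])
    got = [(i.start, i.end) for i in subtract(a, b)]
    assert got == [(0, 20), (30, 50), (60, 100)]

    wins = make_windows({"chr1": 950}, 300)
    assert [(w.start, w.end) for w in wins] == [(0, 300), (300, 600), (600, 900), (900, 950)]

    hits = overlaps_any(IntervalSet([iv(25, 26), iv(40, 45)]), b)
    assert hits.tolist() == [True, False]


def test_interval_validation():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("", 0, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 10)
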